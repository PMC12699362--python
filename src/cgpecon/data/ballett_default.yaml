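# Default model configuration: advanced pan-cancer CGP cohort, n = 814.
#
# Pathway counts are nested stratum sizes per tumor type
# (count >= success >= actionable >= mtb_rec >= matched >= on_label);
# total_diagnostic_cost calibrates the per-type repeat-test multiplier
# against the CGP and MTB unit costs.
cohort:
  n_patients: 814
  p_other_given_unmatched: 0.85
  tier_weights: {"1A": 0.25, "1B": 0.15, "2C": 0.35, "2D": 0.25}
  tumor_types:
    lung:    {count: 76,  success: 71,  actionable: 66,  mtb_rec: 62,  matched: 16, on_label: 7,  total_diagnostic_cost: 159232}
    breast:  {count: 120, success: 112, actionable: 105, mtb_rec: 88,  matched: 22, on_label: 8,  total_diagnostic_cost: 257221}
    colon:   {count: 86,  success: 81,  actionable: 65,  mtb_rec: 54,  matched: 9,  on_label: 0,  total_diagnostic_cost: 179647}
    sarcoma: {count: 53,  success: 50,  actionable: 29,  mtb_rec: 21,  matched: 8,  on_label: 0,  total_diagnostic_cost: 120445}
    other:   {count: 479, success: 449, actionable: 356, mtb_rec: 304, matched: 68, on_label: 18, total_diagnostic_cost: 1031139}
  upfront:
    # SOC-diagnostics indication quota per pathway stratum (sums to 422)
    indication_by_stratum:
      on_label: 26
      investigational: 48
      rec_unmatched: 238
      actionable_no_rec: 28
      success_no_actionable: 74
      no_success: 8
    # SOC-guideline-actionable and SOC-phase-matched quotas per
    # (stratum, indication) cell
    soc_cells:
      on_label:
        indicated:     {soc_actionable: 22,  soc_phase_matched: 22}
        non_indicated: {soc_actionable: 0,   soc_phase_matched: 0}
      investigational:
        indicated:     {soc_actionable: 20,  soc_phase_matched: 20}
        non_indicated: {soc_actionable: 10,  soc_phase_matched: 10}
      rec_unmatched:
        indicated:     {soc_actionable: 173, soc_phase_matched: 93}
        non_indicated: {soc_actionable: 76,  soc_phase_matched: 62}
    # targets detected only by the upfront panel (HRD extension), per
    # indication stratum
    extra_actionable: {indicated: 19, non_indicated: 18}
costs:
  cgp_unit_cost: 1831.94
  mtb_unit_cost: 209.50
  # per SOC-indicated patient (349235 / 422)
  soc_unit_cost_indicated: 827.5710900474
  # upfront-scenario mean add-on per patient, by indication stratum
  upfront_cgp_addon: {indicated: 115.6855924171, non_indicated: 105.5906122449}
  usd_factor: 1.15
  mtb_per_patient: true
analysis:
  wtp_per_matched: 5000.0
  wtp_per_qaly: 40000.0
psa:
  n_iterations: 1000
  se_fraction: 0.10
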