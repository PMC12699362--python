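# Methods

## Model

The package implements a cohort decision tree of the CGP diagnostic
pathway in advanced solid cancer. Patients enter at the CGP test and are
resolved sequentially: test success → detection of at least one
actionable target (AMP/ASCO/CAP tier 1A/1B/2C/2D) → molecular tumor
board (MTB) recommendation → one of four mutually exclusive treatment
categories (matched on-label, matched investigational/off-label, other
treatment, no treatment). The time horizon is diagnostic: costs cover
testing (including repeat analyses) and MTB discussion only; treatment
costs, survival and discounting are out of scope by construction.

Assumptions worth making explicit:

- **Repeat testing is a cost multiplier, not a pathway branch.** The
  expected per-patient cost is `c_CGP·(1+p_repeat) + c_MTB`; the outcome
  chain is unaffected by repeats.
- **MTB cost is allocated per patient** by default, matching the
  published per-patient estimate. The alternative allocation (only
  patients actually discussed, weighting the MTB term by P(MTB rec)) is
  available via `CostModel(mtb_per_patient=False)`. Under the default
  allocation the analytic CGP-cost break-even at WTP €5000 lands at
  ≈€516 rather than the published €507; the two values differ by 1.8%
  and the published cost-allocation detail needed to close the gap is
  not public, so no attempt is made to force agreement.
- **The zero-comparator** (no further diagnostics, zero cost, zero
  diagnostic outcomes) is the base-case comparator, reflecting the
  last-resort setting in which standard-of-care diagnostics are already
  exhausted.

## Calibration of the default configuration

The shipped configuration (`cgpecon/data/ballett_default.yaml`) encodes
the 814-patient cohort: tumor-type counts (lung 76, breast 120, colon
86, sarcoma 53, other 479) and, per type, the nested pathway counts
(success ≥ actionable ≥ MTB-recommended ≥ matched ≥ on-label). Pooled,
these give 763/621/529/123/33 and the conditional chain
p(success)=763/814, p(actionable|success)=621/763, p(rec|actionable)=
529/621, p(matched|rec)=123/529. Counts not individually published (per-
type success; the split of the 'other' stratum) were chosen by
largest-remainder apportionment of the pooled rates, constrained to
reproduce every published per-type outcome count simultaneously.

Per-type repeat-test multipliers are calibrated continuously from the
published per-type total diagnostic costs via
`calibrate_repeat_multiplier` (e.g. lung: (159 232/76 − 209.50)/1831.94
= 1.0293), because the repeat probabilities themselves are not public.
This keeps per-type mean costs — and hence the lung cost-per-matched of
exactly €9952 — free of integer-count quantisation. Record-level repeat
flags carry the same rates, rounded by largest remainder, and are what
`estimate_probabilities` reports.

The expected matched-treatment ICCR of the calibrated chain is €14 209
(1 747 684/123). The corresponding published figure (€14 249) implies a
fractional expected count of 122.65 from unpublished branch parameters;
the difference (0.3%) propagates to the derived quantities within their
stated tolerances.

### Unpublished quantities with chosen defaults

- `p_other_given_unmatched = 0.85`: share of unmatched patients receiving
  some non-molecular-informed treatment rather than none. Most advanced-
  cancer patients in such cohorts still receive chemo-, immuno- or
  hormonal therapy; the value only labels the two unmatched categories
  and never affects costs or the four reported outcomes.
- Tier composition weights (1A 0.25, 1B 0.15, 2C 0.35, 2D 0.25) are
  illustrative: tier identity only gates the actionable flag.
- The successive-matched mechanism (a SOC-phase on-label match followed
  by an investigational matched treatment, counted twice in the upfront
  scenario) is realised as the overlap of SOC-phase matches with the
  investigational category; its size (30 patients) follows from the quota
  table below.

## Synthetic cohort generator

`expected` mode resolves every branch by largest-remainder rounding
(ties broken by declaration order), nested along the chain so monotone
strata are exact prefixes; it is deterministic and seed-independent.
`sampled` mode draws each patient independently along the same
conditional chain from a seeded generator; marginal frequencies converge
to the chain products (tested at n=10⁵ within 3 binomial SEs).

The upfront-scenario flags (SOC-diagnostics indication, SOC-guideline
actionability, SOC-phase matched treatment) are correlated with the
pathway stratum and with each other, so the generator carries them as an
explicit quota table per (stratum × indication) cell rather than as
marginal fractions. The default table reproduces: 422 indicated
patients, 301 SOC-actionable (215 indicated), 207 SOC-phase matched (135
indicated), upfront-CGP matched-treatment units 308 overall and 187 in
the indicated subgroup, and on-label units 218/139. Cell values not
individually published were chosen to satisfy all published scenario-row
percentages at once. The extra actionable targets found only by the
upfront panel (HRD extension; 37 = 19 indicated + 18 not) are an
evaluation-time uplift, not a record flag, keeping the cohort CSV schema
stable. The quota table is count-based for the configured cohort size;
rescaled cohorts drop it (with a log notice) unless rescaled quotas are
supplied.

What the generator does **not** emulate: variant-level genomics (genes,
VAFs, panels), per-patient cost heterogeneity beyond the repeat flag,
time-to-event structure, and any correlation of SOC flags with tumor
type (not published). Passing tests therefore demonstrate fidelity of
the *pathway-level statistical structure*, not of any genomic data.

## Probabilistic sensitivity analysis

Sampling is at the conditional-branch level: independent betas per
branch (parameters = observed stratum successes/failures, add-one
smoothed when a count is zero), Dirichlet splits for the terminal
categories conditional on matched/unmatched, and gammas for the two cost
components with shape 1/SE² (= 100 at the default 10% SE) and scale
mean·SE². This factorisation guarantees matched ≤ recommended ≤
actionable in every draw without rejection. The published factorisation
is not available; the reproduced 95% intervals (matched percentage
≈[12.8, 17.4] vs published [12.5, 17.4]; mean cost ≈[1800, 2557] vs
[1793, 2556] at 1000 iterations) agree within Monte-Carlo tolerance.
Each iteration uses a counter-derived substream (`default_rng([seed, i])`),
so results are order-independent and bit-reproducible. Intervals use the
empirical percentile method (linear interpolation), matching the
asymmetric published cost interval; ellipses use the sample mean and
covariance at the χ²(2 df, 0.95) radius.

## Numerical choices

- Break-evens are solved in closed form (the NMB is linear in uptake and
  in each cost); residuals are asserted below 10⁻⁶ €. The two-way
  frontier interpolates linearly between uptake grid points, which is
  exact for a linear NMB.
- Expected counts stay fractional internally; rendering rounds half-up
  to whole euros and whole percents, grouping digits with a plain space
  from five digits up (machine-readable outputs are unformatted).
- Degenerate inputs: empty estimation strata yield `None`
  ("undefined-with-flag") probabilities, which only error if probability
  mass reaches them; ICCRs with non-positive incremental effects are
  flagged, not returned as 0; a break-even uptake above 1 is flagged
  unattainable; a negative CGP-cost break-even is clamped to 0 and
  flagged infeasible; a negative required-QALY numerator returns 0 with
  a dominance warning.

## Problem sizes

The default analyses run at the calibrated cohort size (n=814) with
1000 PSA iterations; the convergence test samples 10⁵ patients. The
whole suite and the acceptance pipeline complete in seconds on one CPU.

## Known limitations

- Subgroup ICCRs other than lung (colon €19 961 vs published €20 377,
  sarcoma €15 056 vs €15 568) agree only approximately: the published
  figures imply fractional per-type matched counts from unpublished
  branch tables, while integer cohort counts are used here.
- The scenario incremental ratios (€13 888 vs €13 936 all patients;
  €10 790 vs €10 483 indicated subgroup) inherit the coarseness of the
  published scenario percentages.
- The SOC guideline gene list is not public; SOC actionability is a
  calibrated generator flag, not derived from genes.
- The model is a cohort tree: no patient-level cost heterogeneity,
  treatment sequencing, or time-to-event structure.
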