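"""Upfront-diagnostics scenario: upfront CGP versus SOC diagnostics.

Positions CGP as an upfront companion diagnostic and compares it with
standard-of-care (SOC) diagnostics on actionable targets, matched
treatments and diagnostic costs.  SOC actionable targets are the CGP
findings surviving the SOC-guideline filter; SOC matched treatments are
those provided during the SOC phase before enrolment.  Under upfront CGP
the matched-treatment outcome counts treatment units over the whole
trajectory: patients matched in either phase count once, and patients
whose CGP informed successive treatments (on-label followed by
investigational) count twice.  The analysis runs on the full cohort or
restricted to patients with a current SOC-diagnostics indication; SOC
costs accrue only to indicated patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .pathway_estimation import CostModel
from .synthetic_cohort import MATCHED_CATEGORIES, PatientRecord

POPULATIONS = ("all", "soc_indicated")

#: Default upfront-CGP extra-actionable rates per indication stratum: the
#: upfront panel (incl. the HRD extension) detects targets beyond the
#: last-resort findings carried on the records.  Rates are expected extra
#: patients per stratum member, from the shipped calibration.
DEFAULT_EXTRA_ACTIONABLE_RATE: Mapping[bool, float] = {
    True: 19.0 / 422.0,
    False: 18.0 / 392.0,
}


@dataclass(frozen=True)
class ScenarioResult:
    """Outcomes and costs of one strategy within one population."""

    strategy: str                       # upfront_cgp | upfront_soc
    population: str                     # all | soc_indicated
    n: int
    mean_cost: float
    total_cost: float
    actionable: float
    matched_units: float                # may exceed matched patients (double counting)
    matched_patients: int
    onlabel_units: float
    mtb_rec: int | None                 # CGP only; not estimated for SOC
    incremental_cost_per_additional_match: float | None = None
    incremental_flag: str | None = None

    @property
    def pct_actionable(self) -> float:
        return 100.0 * self.actionable / self.n

    @property
    def pct_matched(self) -> float:
        return 100.0 * self.matched_units / self.n

    @property
    def pct_onlabel_matched(self) -> float:
        return 100.0 * self.onlabel_units / self.n

    @property
    def pct_mtb_rec(self) -> float | None:
        return None if self.mtb_rec is None else 100.0 * self.mtb_rec / self.n


def apply_soc_filter(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Per-patient SOC outcome flags after the SOC-guideline filter.

    SOC-strategy actionable targets are the records' ``soc_actionable``
    flags (CGP findings restricted to SOC guideline scope); SOC matched
    treatments are the ``soc_phase_matched`` flags only.  The nesting
    invariants (SOC-actionable within actionable, SOC-matched within
    SOC-actionable) are validated, naming the offending record.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    for r in cohort:
        r.validate()  # includes the soc_* nesting invariants
    return pd.DataFrame({
        "patient_id": [r.patient_id for r in cohort],
        "soc_indication": [r.soc_indication for r in cohort],
        "soc_actionable": [r.soc_actionable for r in cohort],
        "soc_matched": [r.soc_phase_matched for r in cohort],
    })


def evaluate_scenario(cohort: Sequence[PatientRecord], cm: CostModel,
                      population: str = "all",
                      extra_actionable_rate: Mapping[bool, float] | None = None,
                      ) -> tuple[ScenarioResult, ScenarioResult]:
    """Evaluate (upfront CGP, upfront SOC) for one population.

    Upfront CGP carries no repeat testing; its per-patient cost is the
    CGP unit cost plus the MTB cost plus the per-indication-stratum
    upfront add-on.  SOC costs accrue only to SOC-indicated patients, so
    the SOC total is identical across the two populations.
    """
    if population not in POPULATIONS:
        raise ValueError(f"population must be one of {POPULATIONS}, got {population!r}")
    soc_flags = apply_soc_filter(cohort)  # validates the cohort
    if extra_actionable_rate is None:
        extra_actionable_rate = DEFAULT_EXTRA_ACTIONABLE_RATE

    if population == "soc_indicated":
        subset = [r for r in cohort if r.soc_indication]
        if not subset:
            raise ValueError("no SOC-indicated patients in cohort")
    else:
        subset = list(cohort)
    n = len(subset)
    n_ind = sum(r.soc_indication for r in subset)
    n_non = n - n_ind

    # --- upfront CGP -------------------------------------------------
    matched_any = [r for r in subset
                   if r.soc_phase_matched or r.treatment_category in MATCHED_CATEGORIES]
    successive = sum(r.successive_matched for r in subset)
    matched_units = float(len(matched_any) + successive)
    onlabel_units = float(sum(
        r.soc_phase_matched or r.treatment_category == "on_label_matched"
        for r in subset))
    extra = (extra_actionable_rate.get(True, 0.0) * n_ind
             + extra_actionable_rate.get(False, 0.0) * n_non)
    cgp_total = sum(
        cm.cgp_unit_cost + cm.mtb_unit_cost + cm.addon_for(r.soc_indication)
        for r in subset)
    cgp = ScenarioResult(
        strategy="upfront_cgp",
        population=population,
        n=n,
        mean_cost=cgp_total / n,
        total_cost=cgp_total,
        actionable=sum(r.has_actionable for r in subset) + extra,
        matched_units=matched_units,
        matched_patients=len(matched_any),
        onlabel_units=onlabel_units,
        mtb_rec=sum(r.mtb_recommendation for r in subset),
    )

    # --- upfront SOC -------------------------------------------------
    # SOC costs accrue to every SOC-indicated patient in the cohort,
    # independent of the population restriction
    soc_total = float(soc_flags["soc_indication"].sum()) * cm.soc_unit_cost_indicated
    soc_matched = sum(r.soc_phase_matched for r in subset)
    soc = ScenarioResult(
        strategy="upfront_soc",
        population=population,
        n=n,
        mean_cost=soc_total / n,
        total_cost=soc_total,
        actionable=float(sum(r.soc_actionable for r in subset)),
        matched_units=float(soc_matched),
        matched_patients=soc_matched,
        onlabel_units=float(soc_matched),  # SOC-phase matches are on-label
        mtb_rec=None,
    )

    delta_matches = cgp.matched_units - soc.matched_units
    if delta_matches > 0:
        ratio = (cgp.total_cost - soc.total_cost) / delta_matches
        cgp = _with_incremental(cgp, ratio, None)
    else:
        cgp = _with_incremental(cgp, None, "no additional matches")
    return cgp, soc


def _with_incremental(result: ScenarioResult, ratio: float | None,
                      flag: str | None) -> ScenarioResult:
    from dataclasses import replace
    return replace(result, incremental_cost_per_additional_match=ratio,
                   incremental_flag=flag)
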