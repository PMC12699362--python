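"""Branch-probability estimation and the diagnostic cost model.

The decision tree is parameterised by conditional branch probabilities
(estimated from patient-level records by stratum-count ratios) and a
small cost model: the CGP unit cost, a repeat-test multiplier capturing
repeated CGP analyses, and the per-patient molecular-tumor-board (MTB)
cost.  Treatment costs never enter — the model has a diagnostic time
horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .synthetic_cohort import (
    MATCHED_CATEGORIES,
    PatientRecord,
    CohortValidationError,
)

_PROB_FIELDS = (
    "p_success",
    "p_repeat",
    "p_actionable_given_success",
    "p_rec_given_actionable",
    "p_matched_given_rec",
    "p_onlabel_given_matched",
    "p_other_given_unmatched",
)


@dataclass(frozen=True)
class PathwayProbabilities:
    """Conditional branch probabilities of the diagnostic-pathway tree.

    A probability whose denominator stratum was empty is ``None``
    ("undefined-with-flag"), never silently 0.
    """

    p_success: float | None
    p_repeat: float | None
    p_actionable_given_success: float | None
    p_rec_given_actionable: float | None
    p_matched_given_rec: float | None
    p_onlabel_given_matched: float | None
    p_other_given_unmatched: float | None

    def __post_init__(self) -> None:
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(n for n in _PROB_FIELDS if getattr(self, n) is None)

    # Marginal chain products ------------------------------------------
    def _req(self, *names: str) -> list[float]:
        vals = []
        for n in names:
            v = getattr(self, n)
            if v is None:
                raise ValueError(f"probability {n} is undefined (empty stratum)")
            vals.append(v)
        return vals

    @property
    def p_actionable_marginal(self) -> float:
        a, b = self._req("p_success", "p_actionable_given_success")
        return a * b

    @property
    def p_rec_marginal(self) -> float:
        (c,) = self._req("p_rec_given_actionable")
        return self.p_actionable_marginal * c

    @property
    def p_matched_marginal(self) -> float:
        (d,) = self._req("p_matched_given_rec")
        return self.p_rec_marginal * d

    def terminal_category_probabilities(self) -> dict[str, float]:
        """Probabilities of the four mutually exclusive treatment categories."""
        p_m = self.p_matched_marginal
        p_on, p_other = self._req("p_onlabel_given_matched",
                                  "p_other_given_unmatched")
        probs = {
            "on_label_matched": p_m * p_on,
            "investigational_matched": p_m * (1.0 - p_on),
            "other_treatment": (1.0 - p_m) * p_other,
            "no_treatment": (1.0 - p_m) * (1.0 - p_other),
        }
        assert abs(sum(probs.values()) - 1.0) < 1e-12
        return probs


def estimate_probabilities(cohort: Sequence[PatientRecord]) -> PathwayProbabilities:
    """Estimate the branch chain from patient-level records.

    Each conditional probability is the count ratio within its stratum;
    empty strata yield ``None`` rather than 0.  Records violating the
    pathway invariants are rejected, naming the first offender.
    """
    if not cohort:
        raise CohortValidationError("cohort is empty")
    for record in cohort:
        record.validate()
    n = len(cohort)
    success = [r for r in cohort if r.cgp_success]
    actionable = [r for r in success if r.has_actionable]
    rec = [r for r in actionable if r.mtb_recommendation]
    matched = [r for r in rec if r.treatment_category in MATCHED_CATEGORIES]
    onlabel = [r for r in matched if r.treatment_category == "on_label_matched"]
    unmatched = [r for r in cohort if r.treatment_category not in MATCHED_CATEGORIES]
    other = [r for r in unmatched if r.treatment_category == "other_treatment"]
    repeat = [r for r in cohort if r.repeat_test]

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return PathwayProbabilities(
        p_success=ratio(len(success), n),
        p_repeat=ratio(len(repeat), n),
        p_actionable_given_success=ratio(len(actionable), len(success)),
        p_rec_given_actionable=ratio(len(rec), len(actionable)),
        p_matched_given_rec=ratio(len(matched), len(rec)),
        p_onlabel_given_matched=ratio(len(onlabel), len(matched)),
        p_other_given_unmatched=ratio(len(other), len(unmatched)),
    )


# ---------------------------------------------------------------------------
# Cost model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CostModel:
    """Unit costs defining the per-patient diagnostic cost.

    ``repeat_multiplier`` is ``1 + P(repeat CGP analysis)``: repeated test
    costs are included by multiplying the CGP unit cost with the repeat
    probability.  ``mtb_per_patient`` selects the MTB-cost allocation:
    per patient (default) or only for patients discussed at the MTB.
    Scenario-analysis costs (SOC diagnostics, the upfront CGP add-on for
    the HRD panel extension) ride along so that one object configures
    every analysis; USD values appear only in rendered reports.
    """

    cgp_unit_cost: float
    repeat_multiplier: float = 1.0
    mtb_unit_cost: float = 0.0
    soc_unit_cost_indicated: float = 0.0
    upfront_cgp_addon: float = 0.0
    upfront_cgp_addon_by_indication: Mapping[bool, float] | None = None
    usd_factor: float = 1.15
    mtb_per_patient: bool = True
    subgroup_repeat_multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("cgp_unit_cost", "mtb_unit_cost", "soc_unit_cost_indicated",
                     "upfront_cgp_addon", "usd_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.repeat_multiplier < 1.0:
            raise ValueError(
                f"repeat_multiplier must be >= 1, got {self.repeat_multiplier}")

    def with_repeat_multiplier(self, multiplier: float) -> "CostModel":
        return replace(self, repeat_multiplier=multiplier)

    def addon_for(self, indicated: bool) -> float:
        if self.upfront_cgp_addon_by_indication is not None:
            return self.upfront_cgp_addon_by_indication[indicated]
        return self.upfront_cgp_addon


def calibrate_repeat_multiplier(mean_cost_target: float, cgp_unit_cost: float,
                                mtb_unit_cost: float) -> float:
    """Back out the repeat-test multiplier from a known mean diagnostic cost.

    Solves ``cgp_unit_cost * m + mtb_unit_cost = mean_cost_target`` for
    ``m``.  The repeat probability itself is ``m - 1``; a result below 1
    (negative implied repeat probability) is returned with a warning.
    """
    if cgp_unit_cost <= 0:
        raise ValueError(f"cgp_unit_cost must be > 0, got {cgp_unit_cost}")
    if mean_cost_target < mtb_unit_cost:
        raise ValueError(
            f"mean_cost_target ({mean_cost_target}) below mtb_unit_cost "
            f"({mtb_unit_cost})")
    multiplier = (mean_cost_target - mtb_unit_cost) / cgp_unit_cost
    if multiplier < 1.0:
        warnings.warn(
            f"calibrated repeat multiplier {multiplier:.4f} < 1 implies a "
            "negative repeat probability", stacklevel=2)
    return multiplier


def per_patient_diagnostic_cost(cm: CostModel,
                                probs: PathwayProbabilities | None = None) -> float:
    """Expected diagnostic cost per patient entering the pathway.

    ``cgp_unit_cost * repeat_multiplier + mtb_unit_cost``; under the
    discussed-patients MTB allocation the MTB term is weighted by the
    marginal MTB-recommendation probability (``probs`` required then).
    Treatment costs never enter.
    """
    test_cost = cm.cgp_unit_cost * cm.repeat_multiplier
    if cm.mtb_per_patient:
        return test_cost + cm.mtb_unit_cost
    if probs is None:
        raise ValueError(
            "mtb_per_patient=False requires pathway probabilities to weight "
            "the MTB cost by the discussed fraction")
    return test_cost + cm.mtb_unit_cost * probs.p_rec_marginal


def default_cost_model() -> CostModel:
    """The shipped default cost calibration."""
    from .cli_reports import load_run_config  # deferred: avoids import cycle
    return load_run_config().costs
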