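"""Decision-tree propagation: expected costs and diagnostic outcomes.

Propagates a probability chain (or a patient-level cohort) through the
sequential diagnostic pathway — CGP test, actionable-target detection,
MTB recommendation, treatment-category allocation — and returns expected
counts and diagnostic costs, overall or per tumor type.  Expected counts
stay real-valued; rounding to integers happens only when reports are
rendered.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .pathway_estimation import (
    CostModel,
    PathwayProbabilities,
    estimate_probabilities,
    per_patient_diagnostic_cost,
)
from .synthetic_cohort import TUMOR_TYPES, PatientRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortOutcome:
    """Expected costs and outcomes of one cohort propagated through the tree."""

    n: int
    mean_cost: float
    total_cost: float
    expected_actionable: float
    expected_mtb_rec: float
    expected_matched: float
    expected_onlabel: float
    category_probabilities: Mapping[str, float]

    def __post_init__(self) -> None:
        if not math.isclose(self.total_cost, self.n * self.mean_cost,
                            rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("total_cost must equal n * mean_cost")
        chain = (self.expected_onlabel, self.expected_matched,
                 self.expected_mtb_rec, self.expected_actionable, float(self.n))
        for low, high in zip(chain, chain[1:]):
            if low > high + 1e-9 or low < -1e-9:
                raise ValueError(
                    "expected counts must satisfy 0 <= on-label <= matched <= "
                    f"MTB rec <= actionable <= n, got {chain}")
        total_p = sum(self.category_probabilities.values())
        if not math.isclose(total_p, 1.0, abs_tol=1e-9):
            raise ValueError(f"category probabilities sum to {total_p}, not 1")

    # Percentages on the 0-100 scale, as rendered in reports -----------
    @property
    def pct_actionable(self) -> float:
        return 100.0 * self.expected_actionable / self.n

    @property
    def pct_mtb_rec(self) -> float:
        return 100.0 * self.expected_mtb_rec / self.n

    @property
    def pct_matched(self) -> float:
        return 100.0 * self.expected_matched / self.n

    @property
    def pct_onlabel(self) -> float:
        return 100.0 * self.expected_onlabel / self.n

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_cost": self.mean_cost,
            "total_cost": self.total_cost,
            "expected_actionable": self.expected_actionable,
            "expected_mtb_rec": self.expected_mtb_rec,
            "expected_matched": self.expected_matched,
            "expected_onlabel": self.expected_onlabel,
            "category_probabilities": dict(self.category_probabilities),
        }


def evaluate_tree(probs: PathwayProbabilities, cm: CostModel,
                  n: int) -> CohortOutcome:
    """Propagate ``n`` patients through the tree under ``probs`` and ``cm``.

    Expected counts are ``n`` times the chained branch products.  An
    undefined (empty-stratum) probability is an error only if probability
    mass actually reaches that branch.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")

    def branch(upstream_mass: float, name: str) -> float:
        value = getattr(probs, name)
        if value is None:
            if upstream_mass > 0:
                raise ValueError(
                    f"branch {name} is undefined but receives probability "
                    f"mass {upstream_mass:.6g}")
            return 0.0
        return value

    p_s = branch(1.0, "p_success")
    p_a = p_s * branch(p_s, "p_actionable_given_success")
    p_r = p_a * branch(p_a, "p_rec_given_actionable")
    p_m = p_r * branch(p_r, "p_matched_given_rec")
    p_on = p_m * branch(p_m, "p_onlabel_given_matched")
    p_other_given_unmatched = branch(1.0 - p_m, "p_other_given_unmatched")

    categories = {
        "on_label_matched": p_on,
        "investigational_matched": p_m - p_on,
        "other_treatment": (1.0 - p_m) * p_other_given_unmatched,
        "no_treatment": (1.0 - p_m) * (1.0 - p_other_given_unmatched),
    }
    mean_cost = per_patient_diagnostic_cost(cm, probs)
    return CohortOutcome(
        n=n,
        mean_cost=mean_cost,
        total_cost=n * mean_cost,
        expected_actionable=n * p_a,
        expected_mtb_rec=n * p_r,
        expected_matched=n * p_m,
        expected_onlabel=n * p_on,
        category_probabilities=categories,
    )


def evaluate_by_subgroup(cohort: Sequence[PatientRecord], cm: CostModel,
                         grouping: str = "tumor_type",
                         ) -> dict[str, CohortOutcome]:
    """Estimate and evaluate the tree separately per subgroup.

    For each subgroup the branch chain is re-estimated from its records;
    the repeat-test multiplier comes from ``cm.subgroup_repeat_multipliers``
    when the subgroup is calibrated there, otherwise from the subgroup's
    own repeat-test flags.  Subgroups with no members are omitted with a
    log notice.
    """
    if grouping != "tumor_type":
        raise ValueError(f"unsupported grouping {grouping!r}")
    if not cohort:
        raise ValueError("cohort is empty")
    out: dict[str, CohortOutcome] = {}
    for group in TUMOR_TYPES:
        members = [r for r in cohort if r.tumor_type == group]
        if not members:
            logger.info("subgroup %r has no members; omitted", group)
            continue
        probs = estimate_probabilities(members)
        if group in cm.subgroup_repeat_multipliers:
            sub_cm = cm.with_repeat_multiplier(cm.subgroup_repeat_multipliers[group])
        elif probs.p_repeat is not None:
            sub_cm = cm.with_repeat_multiplier(1.0 + probs.p_repeat)
        else:
            sub_cm = cm
        out[group] = evaluate_tree(probs, sub_cm, len(members))
    return out
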