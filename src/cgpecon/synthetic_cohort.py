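"""Synthetic patient cohorts for the CGP diagnostic-pathway model.

Generates patient-level cohorts with the statistical structure of an
advanced pan-cancer comprehensive-genomic-profiling (CGP) programme:
CGP testing (with possible repeat analysis), actionable-target detection
(AMP/ASCO/CAP tier 1A/1B/2C/2D), molecular tumor board (MTB)
recommendation, and allocation to one of four mutually exclusive
treatment categories.  Standard-of-care (SOC) diagnostic flags carried by
each record support the upfront-diagnostics scenario analysis.

Two modes are supported:

``expected``
    Deterministic expected-counts cohort: every branch of the pathway is
    resolved by largest-remainder rounding of ``n x chained branch
    probabilities``, so repeated calls are identical and seed-independent.
``sampled``
    Independent per-patient Monte-Carlo draws along the same conditional
    chain, reproducible from the configured seed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

TUMOR_TYPES = ("lung", "breast", "colon", "sarcoma", "other")
TREATMENT_CATEGORIES = (
    "on_label_matched",
    "investigational_matched",
    "other_treatment",
    "no_treatment",
)
MATCHED_CATEGORIES = ("on_label_matched", "investigational_matched")
TIERS = ("1A", "1B", "2C", "2D")

#: Pathway strata used for the upfront-scenario flag calibration, in the
#: order patients are laid out within each tumor type in expected mode.
STRATA = (
    "on_label",
    "investigational",
    "rec_unmatched",
    "actionable_no_rec",
    "success_no_actionable",
    "no_success",
)

CSV_HEADER = (
    "patient_id",
    "tumor_type",
    "cgp_success",
    "repeat_test",
    "has_actionable",
    "tier_set",
    "mtb_recommendation",
    "treatment_category",
    "soc_indication",
    "soc_actionable",
    "soc_phase_matched",
    "successive_matched",
)

_FLAG_COLUMNS = tuple(c for c in CSV_HEADER if c not in
                      ("patient_id", "tumor_type", "tier_set", "treatment_category"))


class CohortValidationError(ValueError):
    """Raised when a record or configuration violates a model invariant."""


# ---------------------------------------------------------------------------
# Patient records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientRecord:
    """One (simulated or observed) patient with diagnostic-pathway flags."""

    patient_id: str
    tumor_type: str
    cgp_success: bool
    repeat_test: bool
    has_actionable: bool
    tier_set: frozenset[str]
    mtb_recommendation: bool
    treatment_category: str
    soc_indication: bool
    soc_actionable: bool
    soc_phase_matched: bool
    successive_matched: bool

    def __post_init__(self) -> None:
        if self.tumor_type not in TUMOR_TYPES:
            raise CohortValidationError(
                f"record {self.patient_id!r}: unknown tumor_type {self.tumor_type!r}")
        if self.treatment_category not in TREATMENT_CATEGORIES:
            raise CohortValidationError(
                f"record {self.patient_id!r}: unknown treatment_category "
                f"{self.treatment_category!r}")
        bad = set(self.tier_set) - set(TIERS)
        if bad:
            raise CohortValidationError(
                f"record {self.patient_id!r}: unknown tiers {sorted(bad)!r}")

    @property
    def matched(self) -> bool:
        return self.treatment_category in MATCHED_CATEGORIES

    def validate(self) -> None:
        """Check the cross-field pathway invariants; raise on the first breach."""
        pid = self.patient_id
        if self.matched and not self.mtb_recommendation:
            raise CohortValidationError(
                f"record {pid!r}: matched treatment without MTB recommendation")
        if self.mtb_recommendation and not self.has_actionable:
            raise CohortValidationError(
                f"record {pid!r}: MTB recommendation without actionable target")
        if self.has_actionable and not self.cgp_success:
            raise CohortValidationError(
                f"record {pid!r}: actionable target without successful CGP")
        if self.soc_actionable and not self.has_actionable:
            raise CohortValidationError(
                f"record {pid!r}: soc_actionable set but has_actionable is not")
        if self.soc_phase_matched and not self.soc_actionable:
            raise CohortValidationError(
                f"record {pid!r}: soc_phase_matched set but soc_actionable is not")
        if bool(self.tier_set) != self.has_actionable:
            raise CohortValidationError(
                f"record {pid!r}: tier_set must be nonempty iff has_actionable")
        if self.successive_matched and not self.matched:
            raise CohortValidationError(
                f"record {pid!r}: successive_matched requires a matched category")


def validate_cohort(cohort: Sequence[PatientRecord]) -> None:
    for record in cohort:
        record.validate()


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_CHAIN_FIELDS = (
    "p_success",
    "p_actionable_given_success",
    "p_rec_given_actionable",
    "p_matched_given_rec",
    "p_onlabel_given_matched",
    "p_repeat",
)


@dataclass(frozen=True)
class TumorTypeConfig:
    """Conditional pathway chain for one tumor type.

    Probabilities are conditional on the previous step of the chain; the
    repeat-test probability is marginal (repeat testing enters costing as
    a multiplier, independent of the outcome chain).
    """

    count: int
    p_success: float
    p_actionable_given_success: float
    p_rec_given_actionable: float
    p_matched_given_rec: float
    p_onlabel_given_matched: float
    p_repeat: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise CohortValidationError(f"count must be >= 0, got {self.count}")
        for name in _CHAIN_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortValidationError(
                    f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def from_counts(cls, count: int, success: int, actionable: int,
                    mtb_rec: int, matched: int, on_label: int,
                    p_repeat: float = 0.0) -> "TumorTypeConfig":
        """Build the conditional chain from nested stratum counts."""
        seq = (count, success, actionable, mtb_rec, matched, on_label)
        names = ("count", "success", "actionable", "mtb_rec", "matched", "on_label")
        for (up_name, up), (lo_name, lo) in zip(zip(names, seq), zip(names[1:], seq[1:])):
            if lo > up:
                raise CohortValidationError(
                    f"{lo_name} ({lo}) exceeds {up_name} ({up})")
        def ratio(num: int, den: int) -> float:
            return num / den if den else 0.0
        return cls(
            count=count,
            p_success=ratio(success, count),
            p_actionable_given_success=ratio(actionable, success),
            p_rec_given_actionable=ratio(mtb_rec, actionable),
            p_matched_given_rec=ratio(matched, mtb_rec),
            p_onlabel_given_matched=ratio(on_label, matched),
            p_repeat=p_repeat,
        )


@dataclass(frozen=True)
class SocCell:
    """SOC-flag quota within one (pathway stratum, indication) cell."""

    soc_actionable: int = 0
    soc_phase_matched: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.soc_phase_matched <= self.soc_actionable:
            raise CohortValidationError(
                "soc_phase_matched must satisfy 0 <= soc_phase_matched <= "
                f"soc_actionable, got ({self.soc_phase_matched}, {self.soc_actionable})")


@dataclass(frozen=True)
class UpfrontConfig:
    """Calibration of the SOC/upfront flags, stratified by pathway stratum.

    The scenario analysis needs the SOC flags to be correlated with both
    the treatment category and the SOC-diagnostics indication; marginal
    fractions cannot encode that, so the calibration is carried as a
    per-stratum quota table.  Quotas are counts for the configured cohort
    size; sampled mode converts them to conditional probabilities.
    """

    #: patients with a current indication for upfront SOC diagnostics, per stratum
    indication_by_stratum: Mapping[str, int]
    #: SOC-actionable / SOC-phase-matched quotas per (stratum, indicated?) cell
    soc_cells: Mapping[str, Mapping[bool, SocCell]]
    #: additional actionable targets detected only by upfront CGP (e.g. the
    #: HRD panel extension), per indication stratum — used by the scenario
    #: evaluation, not materialised as a record flag
    extra_actionable: Mapping[bool, int] = field(
        default_factory=lambda: {True: 0, False: 0})

    def __post_init__(self) -> None:
        for stratum in self.indication_by_stratum:
            if stratum not in STRATA:
                raise CohortValidationError(
                    f"indication_by_stratum: unknown stratum {stratum!r}")
        for stratum in self.soc_cells:
            if stratum not in ("on_label", "investigational", "rec_unmatched",
                               "actionable_no_rec"):
                raise CohortValidationError(
                    f"soc_cells: stratum {stratum!r} is not an actionable stratum")

    @property
    def soc_indication_count(self) -> int:
        return sum(self.indication_by_stratum.values())


@dataclass(frozen=True)
class GeneratorConfig:
    """Full cohort-generator configuration.

    ``tumor_types`` carries one conditional chain per tumor type; the
    pooled chain of the whole cohort is the count-weighted mixture.
    """

    n_patients: int
    tumor_types: Mapping[str, TumorTypeConfig]
    p_other_given_unmatched: float = 0.85
    tier_weights: Mapping[str, float] = field(
        default_factory=lambda: {"1A": 0.25, "1B": 0.15, "2C": 0.35, "2D": 0.25})
    upfront: UpfrontConfig | None = None
    seed: int = 0
    mode: str = "expected"

    def __post_init__(self) -> None:
        if self.mode not in ("expected", "sampled"):
            raise CohortValidationError(f"mode must be expected|sampled, got {self.mode!r}")
        if self.n_patients <= 0:
            raise CohortValidationError(f"n_patients must be positive, got {self.n_patients}")
        unknown = set(self.tumor_types) - set(TUMOR_TYPES)
        if unknown:
            raise CohortValidationError(f"tumor_types: unknown categories {sorted(unknown)}")
        total = sum(tc.count for tc in self.tumor_types.values())
        if total != self.n_patients:
            raise CohortValidationError(
                f"tumor_type_counts sum to {total}, expected n_patients={self.n_patients}")
        if not 0.0 <= self.p_other_given_unmatched <= 1.0:
            raise CohortValidationError(
                f"p_other_given_unmatched must lie in [0, 1], got {self.p_other_given_unmatched}")
        bad = set(self.tier_weights) - set(TIERS)
        if bad:
            raise CohortValidationError(f"tier_weights: unknown tiers {sorted(bad)}")
        if any(w < 0 for w in self.tier_weights.values()) or \
                sum(self.tier_weights.values()) <= 0:
            raise CohortValidationError("tier_weights must be nonnegative with positive sum")

    # Convenience marginals of the shipped calibration -----------------
    @property
    def tumor_type_counts(self) -> dict[str, int]:
        return {t: tc.count for t, tc in self.tumor_types.items()}

    @property
    def soc_indication_count(self) -> int:
        return self.upfront.soc_indication_count if self.upfront else 0

    def _soc_totals(self) -> tuple[float, float]:
        if self.upfront is None:
            return (0.0, 0.0)
        sa = sm = 0
        for cells in self.upfront.soc_cells.values():
            for cell in cells.values():
                sa += cell.soc_actionable
                sm += cell.soc_phase_matched
        return (float(sa), float(sm))

    @property
    def soc_actionable_fraction(self) -> float:
        """SOC-actionable share of actionable patients."""
        sa, _ = self._soc_totals()
        actionable = sum(self.expected_strata()[s] for s in
                         ("on_label", "investigational", "rec_unmatched",
                          "actionable_no_rec"))
        return sa / actionable if actionable else 0.0

    @property
    def soc_phase_matched_fraction(self) -> float:
        """SOC-phase-matched share of SOC-actionable patients."""
        sa, sm = self._soc_totals()
        return sm / sa if sa else 0.0

    @property
    def upfront_matched_fraction(self) -> float:
        """Expected matched-treatment units per patient under upfront CGP."""
        if self.upfront is None:
            return 0.0
        strata = self.expected_strata()
        matched = strata["on_label"] + strata["investigational"]
        _, sm = self._soc_totals()
        v_on = sum(self.upfront.soc_cells.get("on_label", {}).get(ind, SocCell()).soc_phase_matched
                   for ind in (True, False))
        v_inv = sum(self.upfront.soc_cells.get("investigational", {}).get(ind, SocCell()).soc_phase_matched
                    for ind in (True, False))
        # union of BALLETT-phase and SOC-phase matches, plus successive double counts
        units = matched + sm - (v_on + v_inv) + v_inv
        return units / self.n_patients

    def expected_strata(self) -> dict[str, float]:
        """Expected pathway-stratum sizes under the configured mixture chain."""
        out = dict.fromkeys(STRATA, 0.0)
        for tc in self.tumor_types.values():
            s = tc.count * tc.p_success
            a = s * tc.p_actionable_given_success
            r = a * tc.p_rec_given_actionable
            m = r * tc.p_matched_given_rec
            o = m * tc.p_onlabel_given_matched
            out["on_label"] += o
            out["investigational"] += m - o
            out["rec_unmatched"] += r - m
            out["actionable_no_rec"] += a - r
            out["success_no_actionable"] += s - a
            out["no_success"] += tc.count - s
        return out


# ---------------------------------------------------------------------------
# Largest-remainder rounding
# ---------------------------------------------------------------------------

def largest_remainder(weights: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Sum-preserving; ties in the fractional remainders are broken by
    declaration order of the categories.
    """
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise CohortValidationError("largest_remainder: weights must have positive sum")
    quota = w / w.sum() * total
    base = np.floor(quota).astype(int)
    leftover = total - int(base.sum())
    # stable sort => earlier categories win exact ties
    order = np.argsort(-(quota - base), kind="stable")
    for idx in order[:leftover]:
        base[idx] += 1
    return base.tolist()


def _lr_binary(total: int, p: float) -> int:
    """Largest-remainder count of 'successes' in a binary split."""
    if total == 0:
        return 0
    return largest_remainder([p, 1.0 - p], total)[0]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> list[PatientRecord]:
    """Generate a cohort of :class:`PatientRecord` according to ``config``."""
    if config.mode == "expected":
        cohort = _generate_expected(config)
    else:
        cohort = _generate_sampled(config)
    validate_cohort(cohort)
    return cohort


def _tier_quotas(config: GeneratorConfig, n_actionable: int) -> list[str]:
    """Deterministic primary-tier sequence for the actionable patients."""
    tiers = [t for t in TIERS if config.tier_weights.get(t, 0.0) > 0]
    weights = [config.tier_weights[t] for t in tiers]
    counts = largest_remainder(weights, n_actionable)
    seq: list[str] = []
    for tier, k in zip(tiers, counts):
        seq.extend([tier] * k)
    return seq


def _generate_expected(config: GeneratorConfig) -> list[PatientRecord]:
    rows: list[dict] = []
    for tumor_type in TUMOR_TYPES:
        tc = config.tumor_types.get(tumor_type)
        if tc is None or tc.count == 0:
            continue
        n = tc.count
        n_success = _lr_binary(n, tc.p_success)
        n_act = _lr_binary(n_success, tc.p_actionable_given_success)
        n_rec = _lr_binary(n_act, tc.p_rec_given_actionable)
        n_match = _lr_binary(n_rec, tc.p_matched_given_rec)
        n_onlabel = _lr_binary(n_match, tc.p_onlabel_given_matched)
        n_repeat = _lr_binary(n, tc.p_repeat)
        n_other = _lr_binary(n - n_match, config.p_other_given_unmatched)
        # lay patients out deepest-in-the-tree first, so nested strata are
        # contiguous prefixes
        strata_sizes = {
            "on_label": n_onlabel,
            "investigational": n_match - n_onlabel,
            "rec_unmatched": n_rec - n_match,
            "actionable_no_rec": n_act - n_rec,
            "success_no_actionable": n_success - n_act,
            "no_success": n - n_success,
        }
        unmatched_seen = 0
        pos = 0
        for stratum in STRATA:
            for _ in range(strata_sizes[stratum]):
                matched = stratum in ("on_label", "investigational")
                if matched:
                    category = ("on_label_matched" if stratum == "on_label"
                                else "investigational_matched")
                else:
                    category = ("other_treatment" if unmatched_seen < n_other
                                else "no_treatment")
                    unmatched_seen += 1
                rows.append({
                    "tumor_type": tumor_type,
                    "stratum": stratum,
                    "cgp_success": stratum != "no_success",
                    "repeat_test": pos < n_repeat,
                    "has_actionable": stratum in (
                        "on_label", "investigational", "rec_unmatched",
                        "actionable_no_rec"),
                    "mtb_recommendation": stratum in (
                        "on_label", "investigational", "rec_unmatched"),
                    "treatment_category": category,
                })
                pos += 1
    _assign_tiers_expected(config, rows)
    _assign_upfront_expected(config, rows)
    return _rows_to_records(rows)


def _assign_tiers_expected(config: GeneratorConfig, rows: list[dict]) -> None:
    actionable = [r for r in rows if r["has_actionable"]]
    seq = _tier_quotas(config, len(actionable))
    for row, tier in zip(actionable, seq):
        row["tier_set"] = frozenset([tier])
    for row in rows:
        row.setdefault("tier_set", frozenset())


def _assign_upfront_expected(config: GeneratorConfig, rows: list[dict]) -> None:
    for row in rows:
        row["soc_indication"] = False
        row["soc_actionable"] = False
        row["soc_phase_matched"] = False
        row["successive_matched"] = False
    up = config.upfront
    if up is None:
        return
    by_stratum: dict[str, list[dict]] = {s: [] for s in STRATA}
    for row in rows:
        by_stratum[row["stratum"]].append(row)
    for stratum, quota in up.indication_by_stratum.items():
        members = by_stratum[stratum]
        if quota > len(members):
            raise CohortValidationError(
                f"indication_by_stratum[{stratum!r}]={quota} exceeds stratum "
                f"size {len(members)}")
        for row in members[:quota]:
            row["soc_indication"] = True
    for stratum, cells in up.soc_cells.items():
        for indicated, cell in cells.items():
            members = [r for r in by_stratum[stratum]
                       if r["soc_indication"] is indicated]
            if cell.soc_actionable > len(members):
                raise CohortValidationError(
                    f"soc_cells[{stratum!r}][indicated={indicated}].soc_actionable="
                    f"{cell.soc_actionable} exceeds cell size {len(members)}")
            for row in members[:cell.soc_phase_matched]:
                row["soc_actionable"] = True
                row["soc_phase_matched"] = True
            for row in members[cell.soc_phase_matched:cell.soc_actionable]:
                row["soc_actionable"] = True
    # successive matched treatment: SOC-phase on-label match followed by an
    # investigational matched treatment in the CGP phase
    for row in rows:
        row["successive_matched"] = (
            row["soc_phase_matched"]
            and row["treatment_category"] == "investigational_matched")


def _sampling_rates(config: GeneratorConfig) -> tuple[dict, dict]:
    """Conditional per-stratum rates implied by the upfront quota table."""
    up = config.upfront
    strata = config.expected_strata()
    p_ind: dict[str, float] = {}
    cell_rates: dict[tuple[str, bool], tuple[float, float]] = {}
    if up is None:
        return {s: 0.0 for s in STRATA}, cell_rates
    for stratum in STRATA:
        quota = up.indication_by_stratum.get(stratum, 0)
        size = strata[stratum]
        p = quota / size if size else 0.0
        if p > 1.0 + 1e-9:
            raise CohortValidationError(
                f"indication_by_stratum[{stratum!r}] implies probability {p:.3f} > 1")
        p_ind[stratum] = min(p, 1.0)
    for stratum, cells in up.soc_cells.items():
        size = strata[stratum]
        for indicated, cell in cells.items():
            cell_n = size * p_ind[stratum] if indicated else size * (1 - p_ind[stratum])
            p_sa = cell.soc_actionable / cell_n if cell_n else 0.0
            p_sm_given_sa = (cell.soc_phase_matched / cell.soc_actionable
                             if cell.soc_actionable else 0.0)
            if p_sa > 1.0 + 1e-9:
                raise CohortValidationError(
                    f"soc_cells[{stratum!r}][indicated={indicated}] implies "
                    f"soc_actionable probability {p_sa:.3f} > 1")
            cell_rates[(stratum, indicated)] = (min(p_sa, 1.0), p_sm_given_sa)
    return p_ind, cell_rates


def _generate_sampled(config: GeneratorConfig) -> list[PatientRecord]:
    rng = np.random.default_rng(config.seed)
    types = [t for t in TUMOR_TYPES if t in config.tumor_types]
    type_p = np.array([config.tumor_types[t].count for t in types], dtype=float)
    type_p /= type_p.sum()
    tiers = [t for t in TIERS if config.tier_weights.get(t, 0.0) > 0]
    tier_p = np.array([config.tier_weights[t] for t in tiers], dtype=float)
    tier_p /= tier_p.sum()
    p_ind, cell_rates = _sampling_rates(config)

    rows: list[dict] = []
    type_draws = rng.choice(len(types), size=config.n_patients, p=type_p)
    for i in range(config.n_patients):
        tc = config.tumor_types[types[type_draws[i]]]
        success = rng.random() < tc.p_success
        actionable = success and rng.random() < tc.p_actionable_given_success
        rec = actionable and rng.random() < tc.p_rec_given_actionable
        matched = rec and rng.random() < tc.p_matched_given_rec
        if matched:
            on_label = rng.random() < tc.p_onlabel_given_matched
            category = "on_label_matched" if on_label else "investigational_matched"
            stratum = "on_label" if on_label else "investigational"
        else:
            category = ("other_treatment"
                        if rng.random() < config.p_other_given_unmatched
                        else "no_treatment")
            if rec:
                stratum = "rec_unmatched"
            elif actionable:
                stratum = "actionable_no_rec"
            elif success:
                stratum = "success_no_actionable"
            else:
                stratum = "no_success"
        indicated = rng.random() < p_ind.get(stratum, 0.0)
        p_sa, p_sm = cell_rates.get((stratum, indicated), (0.0, 0.0))
        soc_actionable = actionable and rng.random() < p_sa
        soc_phase_matched = soc_actionable and rng.random() < p_sm
        rows.append({
            "tumor_type": types[type_draws[i]],
            "cgp_success": success,
            "repeat_test": bool(rng.random() < tc.p_repeat),
            "has_actionable": actionable,
            "tier_set": (frozenset([tiers[rng.choice(len(tiers), p=tier_p)]])
                         if actionable else frozenset()),
            "mtb_recommendation": rec,
            "treatment_category": category,
            "soc_indication": indicated,
            "soc_actionable": soc_actionable,
            "soc_phase_matched": soc_phase_matched,
            "successive_matched": (soc_phase_matched
                                   and category == "investigational_matched"),
        })
    return _rows_to_records(rows)


def _rows_to_records(rows: list[dict]) -> list[PatientRecord]:
    width = max(4, len(str(len(rows))))
    records = []
    for i, row in enumerate(rows, start=1):
        records.append(PatientRecord(
            patient_id=f"P{i:0{width}d}",
            tumor_type=row["tumor_type"],
            cgp_success=bool(row["cgp_success"]),
            repeat_test=bool(row["repeat_test"]),
            has_actionable=bool(row["has_actionable"]),
            tier_set=row["tier_set"],
            mtb_recommendation=bool(row["mtb_recommendation"]),
            treatment_category=row["treatment_category"],
            soc_indication=bool(row["soc_indication"]),
            soc_actionable=bool(row["soc_actionable"]),
            soc_phase_matched=bool(row["soc_phase_matched"]),
            successive_matched=bool(row["successive_matched"]),
        ))
    return records


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_cohort(cohort: Iterable[PatientRecord], destination: str | Path) -> None:
    """Write a cohort to CSV (flags as 0/1, tier_set semicolon-joined)."""
    with open(destination, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in cohort:
            writer.writerow([
                r.patient_id,
                r.tumor_type,
                int(r.cgp_success),
                int(r.repeat_test),
                int(r.has_actionable),
                ";".join(sorted(r.tier_set)),
                int(r.mtb_recommendation),
                r.treatment_category,
                int(r.soc_indication),
                int(r.soc_actionable),
                int(r.soc_phase_matched),
                int(r.successive_matched),
            ])


def read_cohort(source: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV written by :func:`write_cohort`, validating strictly."""
    records: list[PatientRecord] = []
    with open(source, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortValidationError(f"{source}: empty file, expected a header row")
        if tuple(header) != CSV_HEADER:
            unknown = [c for c in header if c not in CSV_HEADER]
            missing = [c for c in CSV_HEADER if c not in header]
            raise CohortValidationError(
                f"{source}: bad header (unknown columns {unknown}, missing {missing})")
        for rownum, values in enumerate(reader, start=1):
            if len(values) != len(CSV_HEADER):
                raise CohortValidationError(
                    f"{source} row {rownum}: expected {len(CSV_HEADER)} fields, "
                    f"got {len(values)}")
            row = dict(zip(CSV_HEADER, values))
            if row["tumor_type"] not in TUMOR_TYPES:
                raise CohortValidationError(
                    f"{source} row {rownum}, column tumor_type: unknown category "
                    f"{row['tumor_type']!r}")
            if row["treatment_category"] not in TREATMENT_CATEGORIES:
                raise CohortValidationError(
                    f"{source} row {rownum}, column treatment_category: unknown "
                    f"category {row['treatment_category']!r}")
            flags = {}
            for col in _FLAG_COLUMNS:
                if row[col] not in ("0", "1"):
                    raise CohortValidationError(
                        f"{source} row {rownum}, column {col}: non-boolean value "
                        f"{row[col]!r} (expected 0 or 1)")
                flags[col] = row[col] == "1"
            tier_tokens = [t for t in row["tier_set"].split(";") if t]
            bad = [t for t in tier_tokens if t not in TIERS]
            if bad:
                raise CohortValidationError(
                    f"{source} row {rownum}, column tier_set: unknown tiers {bad}")
            record = PatientRecord(
                patient_id=row["patient_id"],
                tumor_type=row["tumor_type"],
                tier_set=frozenset(tier_tokens),
                treatment_category=row["treatment_category"],
                **flags,
            )
            try:
                record.validate()
            except CohortValidationError as exc:
                raise CohortValidationError(f"{source} row {rownum}: {exc}") from exc
            records.append(record)
    return records


def default_config(mode: str = "expected", seed: int = 0) -> GeneratorConfig:
    """The shipped default cohort calibration (814 advanced-cancer patients)."""
    from .cli_reports import load_run_config  # deferred: avoids import cycle
    cfg = load_run_config().generator
    return replace(cfg, mode=mode, seed=seed)
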