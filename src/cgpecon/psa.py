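"""Probabilistic sensitivity analysis for the diagnostic-pathway model.

Parameter uncertainty is propagated by Monte Carlo: beta distributions
for the binary branch probabilities (parameterised directly by observed
stratum successes/failures), a Dirichlet for each terminal category
split (on-label vs investigational within matched; other vs none within
unmatched), and gamma distributions for the cost components (mean at the
point estimate, SD a fixed fraction of the mean — 10% where empirical
dispersion is unavailable).  Sampling at the conditional-branch level
guarantees the monotone chain matched <= recommended <= actionable by
construction, without rejection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .decision_tree import CohortOutcome, evaluate_tree
from .pathway_estimation import CostModel, PathwayProbabilities
from .synthetic_cohort import MATCHED_CATEGORIES, PatientRecord

logger = logging.getLogger(__name__)

#: order in which per-iteration random draws are consumed (stable contract
#: for reproducibility)
_BETA_ORDER = ("p_success", "p_actionable_given_success",
               "p_rec_given_actionable", "p_matched_given_rec", "p_repeat")
_GAMMA_ORDER = ("cgp_unit_cost", "mtb_unit_cost")


@dataclass(frozen=True)
class PsaSpec:
    """Calibrated sampling distributions for one PSA run."""

    beta_params: Mapping[str, tuple[float, float]]
    dirichlet_matched: tuple[float, float]      # (on-label, investigational)
    dirichlet_unmatched: tuple[float, float]    # (other treatment, none)
    gamma_params: Mapping[str, tuple[float, float]]  # name -> (shape, scale)
    n_iterations: int = 1000
    seed: int = 0
    se_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.se_fraction <= 0:
            raise ValueError("se_fraction must be > 0")
        for name, (a, b) in self.beta_params.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"beta_params[{name!r}] must be positive, got {(a, b)}")
        for pair in (self.dirichlet_matched, self.dirichlet_unmatched):
            if any(x <= 0 for x in pair):
                raise ValueError(f"Dirichlet parameters must be positive, got {pair}")


@dataclass(frozen=True)
class PsaSummary:
    """Percentile intervals, ellipse parameters and WTP exceedance counts."""

    n_iterations: int
    intervals: Mapping[str, tuple[float, float]]       # 2.5% / 97.5%
    means: Mapping[str, float]
    ellipses: Mapping[str, dict]                       # outcome-vs-cost pairs
    wtp: float
    wtp_exceed_count: int
    degenerate: bool = False


def _stratum_beta(successes: int, failures: int, name: str) -> tuple[float, float]:
    if successes == 0 or failures == 0:
        logger.info("beta stratum %r has a zero count (%d, %d); applying "
                    "add-one smoothing", name, successes, failures)
        return (successes + 1.0, failures + 1.0)
    return (float(successes), float(failures))


def _dirichlet_pair(a: int, b: int, name: str) -> tuple[float, float]:
    if a == 0 or b == 0:
        logger.info("Dirichlet split %r has a zero count (%d, %d); applying "
                    "add-one smoothing", name, a, b)
        return (a + 1.0, b + 1.0)
    return (float(a), float(b))


def calibrate_distributions(cohort: Sequence[PatientRecord], cm: CostModel,
                            n_iterations: int = 1000, seed: int = 0,
                            se_fraction: float = 0.10) -> PsaSpec:
    """Derive the PSA distributions from cohort counts and cost inputs.

    Beta parameters equal the observed stratum successes and failures
    (add-one smoothed when a count is zero); gamma shape/scale solve
    ``mean = point estimate`` and ``SD = se_fraction x mean``, hence
    ``shape = 1/se_fraction^2``.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    n = len(cohort)
    success = sum(r.cgp_success for r in cohort)
    actionable = sum(r.has_actionable for r in cohort)
    rec = sum(r.mtb_recommendation for r in cohort)
    matched = sum(r.treatment_category in MATCHED_CATEGORIES for r in cohort)
    onlabel = sum(r.treatment_category == "on_label_matched" for r in cohort)
    other = sum(r.treatment_category == "other_treatment" for r in cohort)
    repeat = sum(r.repeat_test for r in cohort)

    beta_params = {
        "p_success": _stratum_beta(success, n - success, "p_success"),
        "p_actionable_given_success": _stratum_beta(
            actionable, success - actionable, "p_actionable_given_success"),
        "p_rec_given_actionable": _stratum_beta(
            rec, actionable - rec, "p_rec_given_actionable"),
        "p_matched_given_rec": _stratum_beta(
            matched, rec - matched, "p_matched_given_rec"),
        "p_repeat": _stratum_beta(repeat, n - repeat, "p_repeat"),
    }
    shape = 1.0 / se_fraction ** 2
    gamma_params = {
        "cgp_unit_cost": (shape, cm.cgp_unit_cost / shape),
        "mtb_unit_cost": (shape, cm.mtb_unit_cost / shape),
    }
    return PsaSpec(
        beta_params=beta_params,
        dirichlet_matched=_dirichlet_pair(onlabel, matched - onlabel,
                                          "on-label vs investigational"),
        dirichlet_unmatched=_dirichlet_pair(other, n - matched - other,
                                            "other treatment vs none"),
        gamma_params=gamma_params,
        n_iterations=n_iterations,
        seed=seed,
        se_fraction=se_fraction,
    )


def run_psa(spec: PsaSpec, cm: CostModel, n_patients: int) -> list[CohortOutcome]:
    """Draw ``spec.n_iterations`` parameter sets and propagate each one.

    Iteration ``i`` uses a dedicated counter-derived substream of the
    seeded generator, so results are independent of evaluation order and
    identical seeds give identical output.
    """
    outcomes = []
    for i in range(spec.n_iterations):
        rng = np.random.default_rng([spec.seed, i])
        draws = {name: rng.beta(*spec.beta_params[name]) for name in _BETA_ORDER}
        on_split = rng.dirichlet(spec.dirichlet_matched)
        other_split = rng.dirichlet(spec.dirichlet_unmatched)
        costs = {name: rng.gamma(*spec.gamma_params[name]) for name in _GAMMA_ORDER}
        probs = PathwayProbabilities(
            p_success=draws["p_success"],
            p_repeat=draws["p_repeat"],
            p_actionable_given_success=draws["p_actionable_given_success"],
            p_rec_given_actionable=draws["p_rec_given_actionable"],
            p_matched_given_rec=draws["p_matched_given_rec"],
            p_onlabel_given_matched=float(on_split[0]),
            p_other_given_unmatched=float(other_split[0]),
        )
        cm_i = replace(cm,
                       cgp_unit_cost=costs["cgp_unit_cost"],
                       mtb_unit_cost=costs["mtb_unit_cost"],
                       repeat_multiplier=1.0 + draws["p_repeat"])
        outcomes.append(evaluate_tree(probs, cm_i, n_patients))
    return outcomes


def iterations_frame(iterations: Sequence[CohortOutcome]):
    """Per-iteration table: mean cost, outcome percentages, cost per matched."""
    import pandas as pd

    rows = []
    for out in iterations:
        p_matched = out.expected_matched / out.n
        rows.append({
            "mean_cost": out.mean_cost,
            "pct_actionable": out.pct_actionable,
            "pct_mtb_rec": out.pct_mtb_rec,
            "pct_matched": out.pct_matched,
            "cost_per_matched": (out.mean_cost / p_matched
                                 if p_matched > 0 else math.inf),
        })
    return pd.DataFrame(rows)


def summarize_psa(iterations: Sequence[CohortOutcome], wtp: float) -> PsaSummary:
    """Empirical 95% percentile intervals, 95% ellipses, WTP exceedances."""
    if len(iterations) < 2:
        raise ValueError("at least 2 iterations required for intervals")
    df = iterations_frame(iterations)
    quantities = ("mean_cost", "pct_actionable", "pct_mtb_rec", "pct_matched")
    intervals = {}
    means = {}
    for q in quantities:
        lo, hi = np.percentile(df[q].to_numpy(), [2.5, 97.5],
                               method="linear")
        intervals[q] = (float(lo), float(hi))
        means[q] = float(df[q].mean())
    radius2 = stats.chi2.ppf(0.95, df=2)
    ellipses = {}
    degenerate = False
    for q in ("pct_actionable", "pct_mtb_rec", "pct_matched"):
        xy = df[[q, "mean_cost"]].to_numpy()
        cov = np.cov(xy, rowvar=False)
        if np.linalg.det(cov) <= 1e-300:
            degenerate = True
        ellipses[q] = {
            "mean": xy.mean(axis=0).tolist(),
            "cov": cov.tolist(),
            "radius2": float(radius2),
        }
    exceed = int((df["cost_per_matched"].to_numpy() <= wtp).sum())
    return PsaSummary(
        n_iterations=len(iterations),
        intervals=intervals,
        means=means,
        ellipses=ellipses,
        wtp=wtp,
        wtp_exceed_count=exceed,
        degenerate=degenerate,
    )


def plot_cost_consequence_plane(iterations: Sequence[CohortOutcome], wtp: float,
                                path) -> None:
    """Scatter of the PSA iterations on the cost-consequence plane.

    Outcome percentages against mean diagnostic cost, with 95% ellipses
    and the WTP line (cost = wtp x matched fraction) for reference.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = iterations_frame(iterations)
    summary = summarize_psa(iterations, wtp)
    fig, ax = plt.subplots(figsize=(7, 5))
    colors = {"pct_actionable": "tab:green", "pct_mtb_rec": "tab:orange",
              "pct_matched": "tab:red"}
    labels = {"pct_actionable": "actionable targets",
              "pct_mtb_rec": "MTB recommendations",
              "pct_matched": "matched treatments"}
    for q, color in colors.items():
        ax.scatter(df[q], df["mean_cost"], s=4, alpha=0.3, color=color,
                   label=labels[q])
        ell = summary.ellipses[q]
        mean = np.array(ell["mean"])
        cov = np.array(ell["cov"])
        vals, vecs = np.linalg.eigh(cov)
        theta = np.linspace(0, 2 * np.pi, 200)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        pts = (vecs @ (np.sqrt(np.maximum(vals, 0) * ell["radius2"])[:, None]
                       * circle)).T + mean
        ax.plot(pts[:, 0], pts[:, 1], color=color, lw=1.5)
    pct = np.linspace(0, 100, 50)
    ax.plot(pct, wtp * pct / 100.0, "b:", label=f"WTP EUR {wtp:.0f}/matched")
    ax.set_xlabel("patients with outcome, %")
    ax.set_ylabel("mean diagnostic cost, EUR")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
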