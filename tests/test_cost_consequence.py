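"""ICCRs, net monetary benefit, break-evens and deterministic DSA."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cgpecon as cg
from cgpecon.cost_consequence import RESIDUAL_TOL


def _outcome(n=10, mean_cost=100.0, actionable=4.0, rec=2.0, matched=1.0,
             onlabel=0.5):
    return cg.CohortOutcome(
        n=n, mean_cost=mean_cost, total_cost=n * mean_cost,
        expected_actionable=actionable, expected_mtb_rec=rec,
        expected_matched=matched, expected_onlabel=onlabel,
        category_probabilities={
            "on_label_matched": onlabel / n,
            "investigational_matched": (matched - onlabel) / n,
            "other_treatment": (n - matched) / n,
            "no_treatment": 0.0})


class TestIccr:
    def test_lung_iccr_against_zero_comparator(self, cohort, cost_model):
        lung = cg.evaluate_by_subgroup(cohort, cost_model)["lung"]
        iccr = cg.compute_iccr(lung)
        assert iccr.cost_per_matched == pytest.approx(9952.0, abs=1e-6)

    def test_arithmetic_example(self):
        iccr = cg.compute_iccr(_outcome(n=10, mean_cost=100.0))
        assert (iccr.cost_per_actionable, iccr.cost_per_mtb_rec,
                iccr.cost_per_matched) == (250.0, 500.0, 1000.0)

    def test_zero_matched_flagged_undefined(self):
        iccr = cg.compute_iccr(_outcome(matched=0.0, onlabel=0.0))
        assert iccr.cost_per_matched is None
        assert "cost_per_matched" in iccr.undefined
        assert iccr.cost_per_actionable == 250.0

    def test_scale_invariance_in_n(self, probs, cost_model):
        small = cg.evaluate_tree(probs, cost_model, 10)
        big = cg.evaluate_tree(probs, cost_model, 1000)
        assert cg.compute_iccr(small).cost_per_matched == pytest.approx(
            cg.compute_iccr(big).cost_per_matched)

    def test_explicit_comparator(self):
        a = _outcome(n=10, mean_cost=100.0, matched=2.0, onlabel=1.0)
        b = _outcome(n=10, mean_cost=50.0, matched=1.0, onlabel=0.5)
        iccr = cg.compute_iccr(a, b)
        assert iccr.cost_per_matched == pytest.approx(500.0)


class TestNmb:
    def test_default_outcome_negative_at_wtp_5000(self, probs, cost_model):
        out = cg.evaluate_tree(probs, cost_model, 814)
        nmb = cg.compute_nmb(out, 5000.0)
        assert nmb.nmb_per_patient == pytest.approx(-1391.5, abs=0.5)
        assert nmb.nmb_total == pytest.approx(814 * nmb.nmb_per_patient)

    def test_wtp_zero_is_minus_mean_cost(self):
        out = _outcome()
        assert cg.compute_nmb(out, 0.0).nmb_per_patient == -out.mean_cost

    def test_break_even_identity(self):
        out = _outcome()
        wtp = cg.compute_iccr(out).cost_per_matched
        assert abs(cg.compute_nmb(out, wtp).nmb_per_patient) < 1e-9

    @given(st.floats(0, 50_000))
    def test_sign_duality_with_iccr(self, wtp):
        out = _outcome()
        cpm = cg.compute_iccr(out).cost_per_matched
        nmb = cg.compute_nmb(out, wtp).nmb_per_patient
        assert (nmb > 0) == (wtp > cpm) or math.isclose(wtp, cpm)


class TestBreakEvens:
    def test_uptake_break_even_matches_printed_66pct(self, probs, cost_model):
        be = cg.break_even_uptake(probs, cost_model, 5000.0)
        assert round(100 * be.value) == 66
        assert be.flag is None
        assert abs(be.residual_nmb) < RESIDUAL_TOL

    def test_cgp_cost_break_even_within_2pct_of_printed(self, probs, cost_model):
        be = cg.break_even_cgp_cost(probs, cost_model, 5000.0)
        assert abs(be.value - 507.0) / 507.0 < 0.02
        assert abs(be.residual_nmb) < RESIDUAL_TOL

    def test_uptake_above_one_flagged_unattainable(self):
        probs = cg.PathwayProbabilities(
            p_success=1.0, p_repeat=0.0, p_actionable_given_success=1.0,
            p_rec_given_actionable=0.5, p_matched_given_rec=0.1,
            p_onlabel_given_matched=0.5, p_other_given_unmatched=0.5)
        cm = cg.CostModel(cgp_unit_cost=3000.0, repeat_multiplier=1.0,
                          mtb_unit_cost=0.0)
        be = cg.break_even_uptake(probs, cm, 5000.0)
        assert be.value == pytest.approx(1.2)
        assert be.flag == "unattainable"

    def test_zero_mean_cost_gives_zero_uptake(self, probs):
        cm = cg.CostModel(cgp_unit_cost=0.0, repeat_multiplier=1.0,
                          mtb_unit_cost=0.0)
        assert cg.break_even_uptake(probs, cm, 5000.0).value == 0.0

    def test_mtb_cost_exceeding_benefit_clamped_infeasible(self, probs):
        cm = cg.CostModel(cgp_unit_cost=100.0, repeat_multiplier=1.0,
                          mtb_unit_cost=10_000.0)
        be = cg.break_even_cgp_cost(probs, cm, 5000.0)
        assert be.value == 0.0
        assert be.flag == "infeasible"

    def test_resubstitution_residuals(self, probs, cost_model):
        for wtp in (1000.0, 5000.0, 20_000.0):
            assert abs(cg.break_even_uptake(probs, cost_model, wtp).residual_nmb) \
                < RESIDUAL_TOL


class TestDsa:
    def test_uptake_curve_brackets_break_even(self, probs, cost_model):
        curve = cg.one_way_dsa("uptake", [123 / 529, 0.66], probs, cost_model,
                               5000.0)
        assert curve[0][1] < 0
        assert abs(curve[1][1]) < 15  # near zero at the 66% break-even

    def test_empty_grid(self, probs, cost_model):
        assert cg.one_way_dsa("uptake", [], probs, cost_model, 5000.0) == []

    def test_zero_cgp_cost(self, probs, cost_model):
        (_, nmb), = cg.one_way_dsa("cgp_unit_cost", [0.0], probs, cost_model,
                                   5000.0)
        expected = 5000.0 * probs.p_matched_marginal - cost_model.mtb_unit_cost
        assert nmb == pytest.approx(expected)

    def test_unknown_parameter_rejected(self, probs, cost_model):
        with pytest.raises(ValueError, match="unknown parameter"):
            cg.one_way_dsa("discount_rate", [0.1], probs, cost_model, 5000.0)

    def test_cost_curves_monotone_decreasing(self, probs, cost_model):
        grid = np.linspace(0, 3000, 7)
        for name in ("cgp_unit_cost", "mtb_unit_cost"):
            nmbs = [y for _, y in cg.one_way_dsa(name, grid, probs,
                                                 cost_model, 5000.0)]
            assert all(a > b for a, b in zip(nmbs, nmbs[1:]))

    def test_uptake_curve_monotone_increasing(self, probs, cost_model):
        nmbs = [y for _, y in cg.one_way_dsa("uptake", np.linspace(0, 1, 6),
                                             probs, cost_model, 5000.0)]
        assert all(a < b for a, b in zip(nmbs, nmbs[1:]))


class TestTwoWayDsa:
    def test_frontier_at_1250_is_47pct(self, probs, cost_model):
        uptake_grid = np.linspace(0.0, 1.0, 101)
        _, frontier = cg.two_way_dsa([1250.0], uptake_grid, probs, cost_model,
                                     5000.0)
        (cost, uptake), = frontier
        assert cost == 1250.0
        assert round(100 * uptake) == 47

    def test_zero_cost_zero_mtb_frontier_at_zero(self, probs):
        cm = cg.CostModel(cgp_unit_cost=1.0, repeat_multiplier=1.0,
                          mtb_unit_cost=0.0)
        _, frontier = cg.two_way_dsa([0.0], np.linspace(0, 1, 11), probs, cm,
                                     5000.0)
        assert frontier[0][1] == 0.0

    def test_single_cell_consistent_with_nmb(self, probs, cost_model):
        surface, _ = cg.two_way_dsa([1831.94], [123 / 529], probs, cost_model,
                                    5000.0)
        expected = (5000.0 * probs.p_matched_marginal
                    - (1831.94 * cost_model.repeat_multiplier
                       + cost_model.mtb_unit_cost))
        assert surface[0, 0] == pytest.approx(expected)

    def test_unreachable_cost_has_none_frontier(self, probs, cost_model):
        _, frontier = cg.two_way_dsa([50_000.0], np.linspace(0, 1, 5), probs,
                                     cost_model, 5000.0)
        assert frontier[0][1] is None
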