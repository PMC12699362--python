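"""Cohort generator: expected-counts determinism, sampling, CSV round trip."""

import dataclasses
from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

import cgpecon as cg
from cgpecon.synthetic_cohort import (
    MATCHED_CATEGORIES,
    _lr_binary,
    largest_remainder,
)


def _count(cohort, pred):
    return sum(1 for r in cohort if pred(r))


class TestExpectedMode:
    def test_marginal_counts_match_calibration(self, cohort):
        assert len(cohort) == 814
        assert Counter(r.tumor_type for r in cohort) == {
            "lung": 76, "breast": 120, "colon": 86, "sarcoma": 53, "other": 479}
        assert _count(cohort, lambda r: r.cgp_success) == 763
        assert _count(cohort, lambda r: r.has_actionable) == 621
        assert _count(cohort, lambda r: r.mtb_recommendation) == 529
        assert _count(cohort, lambda r: r.treatment_category in MATCHED_CATEGORIES) == 123
        assert _count(cohort, lambda r: r.soc_indication) == 422
        assert _count(cohort, lambda r: r.soc_actionable) == 301
        assert _count(cohort, lambda r: r.soc_phase_matched) == 207

    def test_deterministic_and_seed_independent(self, run_config, cohort):
        again = cg.generate_cohort(run_config.generator)
        other_seed = cg.generate_cohort(
            dataclasses.replace(run_config.generator, seed=999))
        assert cohort == again == other_seed

    def test_all_records_satisfy_invariants(self, cohort):
        for r in cohort:
            r.validate()
            assert bool(r.tier_set) == r.has_actionable

    def test_all_probabilities_one_gives_full_chain(self):
        tc = cg.TumorTypeConfig(count=10, p_success=1, p_actionable_given_success=1,
                                p_rec_given_actionable=1, p_matched_given_rec=1,
                                p_onlabel_given_matched=1)
        cfg = cg.GeneratorConfig(n_patients=10, tumor_types={"lung": tc})
        for r in cg.generate_cohort(cfg):
            assert r.cgp_success and r.has_actionable and r.mtb_recommendation
            assert r.treatment_category in MATCHED_CATEGORIES


@pytest.fixture(scope="module")
def big_sample(run_config):
    gen = run_config.generator
    n = 100_000
    counts = cg.largest_remainder(
        [tc.count for tc in gen.tumor_types.values()], n)
    types = {t: dataclasses.replace(tc, count=c)
             for (t, tc), c in zip(gen.tumor_types.items(), counts)}
    cfg = dataclasses.replace(gen, n_patients=n, tumor_types=types,
                              upfront=None, mode="sampled", seed=42)
    return cg.generate_cohort(cfg)


class TestSampledMode:
    def test_matched_fraction_within_3_se(self, big_sample):
        p = 123 / 814
        n = len(big_sample)
        se = (p * (1 - p) / n) ** 0.5
        frac = _count(big_sample, lambda r: r.treatment_category
                      in MATCHED_CATEGORIES) / n
        assert abs(frac - p) < 3 * se

    def test_chain_marginals_converge(self, big_sample):
        n = len(big_sample)
        for pred, p in [(lambda r: r.cgp_success, 763 / 814),
                        (lambda r: r.has_actionable, 621 / 814),
                        (lambda r: r.mtb_recommendation, 529 / 814)]:
            se = (p * (1 - p) / n) ** 0.5
            assert abs(_count(big_sample, pred) / n - p) < 3 * se

    def test_same_seed_reproduces(self, run_config):
        cfg = dataclasses.replace(run_config.generator, mode="sampled", seed=7)
        assert cg.generate_cohort(cfg) == cg.generate_cohort(cfg)


class TestConfigValidation:
    def test_tumor_counts_must_sum_to_n(self, run_config):
        with pytest.raises(cg.CohortValidationError, match="n_patients"):
            dataclasses.replace(run_config.generator, n_patients=813)

    def test_probability_out_of_range_names_field(self):
        with pytest.raises(cg.CohortValidationError, match="p_success"):
            cg.TumorTypeConfig(count=5, p_success=1.2,
                               p_actionable_given_success=0.5,
                               p_rec_given_actionable=0.5,
                               p_matched_given_rec=0.5,
                               p_onlabel_given_matched=0.5)

    def test_nested_counts_must_be_monotone(self):
        with pytest.raises(cg.CohortValidationError, match="actionable"):
            cg.TumorTypeConfig.from_counts(10, 8, 9, 2, 1, 0)


class TestLargestRemainder:
    def test_sum_preserving_and_proportional(self):
        assert largest_remainder([1, 1, 1], 10) == [4, 3, 3]
        assert largest_remainder([76, 120, 86, 53, 479], 814) == [76, 120, 86, 53, 479]

    @given(st.lists(st.floats(0.01, 10), min_size=1, max_size=6),
           st.integers(0, 500))
    def test_sum_invariant(self, weights, total):
        counts = largest_remainder(weights, total)
        assert sum(counts) == total
        assert all(c >= 0 for c in counts)

    def test_binary_exact_fractions(self):
        assert _lr_binary(814, 763 / 814) == 763
        assert _lr_binary(0, 0.5) == 0


class TestCsvRoundTrip:
    def test_round_trip_identity(self, cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        cg.write_cohort(cohort[:3], path)
        assert cg.read_cohort(path) == list(cohort[:3])
        assert len(path.read_text().splitlines()) == 4  # header + 3 rows

    def test_full_cohort_round_trip(self, cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        cg.write_cohort(cohort, path)
        assert cg.read_cohort(path) == list(cohort)

    def test_empty_cohort(self, tmp_path):
        path = tmp_path / "empty.csv"
        cg.write_cohort([], path)
        assert cg.read_cohort(path) == []

    def test_wrong_category_spelling_names_row_and_column(self, cohort, tmp_path):
        path = tmp_path / "bad.csv"
        cg.write_cohort(cohort[:3], path)
        text = path.read_text().replace("on_label_matched", "on-label", 1)
        path.write_text(text)
        bad_row = next(i for i, line in enumerate(path.read_text().splitlines())
                       if "on-label" in line)
        with pytest.raises(cg.CohortValidationError) as exc:
            cg.read_cohort(path)
        assert f"row {bad_row}" in str(exc.value)
        assert "treatment_category" in str(exc.value)

    def test_non_boolean_flag_rejected(self, cohort, tmp_path):
        path = tmp_path / "bad.csv"
        cg.write_cohort(cohort[:1], path)
        lines = path.read_text().splitlines()
        fields = lines[1].split(",")
        fields[2] = "yes"  # cgp_success
        path.write_text("\n".join([lines[0], ",".join(fields)]) + "\n")
        with pytest.raises(cg.CohortValidationError, match="row 1.*cgp_success"):
            cg.read_cohort(path)

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,notacolumn\nP1,1\n")
        with pytest.raises(cg.CohortValidationError, match="notacolumn"):
            cg.read_cohort(path)


class TestRecordInvariants:
    def _record(self, **kw):
        base = dict(patient_id="P1", tumor_type="lung", cgp_success=True,
                    repeat_test=False, has_actionable=True,
                    tier_set=frozenset(["1A"]), mtb_recommendation=True,
                    treatment_category="on_label_matched", soc_indication=False,
                    soc_actionable=False, soc_phase_matched=False,
                    successive_matched=False)
        base.update(kw)
        return cg.PatientRecord(**base)

    def test_matched_requires_recommendation(self):
        with pytest.raises(cg.CohortValidationError, match="MTB recommendation"):
            self._record(mtb_recommendation=False).validate()

    def test_tier_set_iff_actionable(self):
        with pytest.raises(cg.CohortValidationError, match="tier_set"):
            self._record(tier_set=frozenset(),).validate()

    def test_soc_actionable_requires_actionable(self):
        with pytest.raises(cg.CohortValidationError, match="soc_actionable"):
            self._record(treatment_category="no_treatment",
                         mtb_recommendation=False, has_actionable=False,
                         tier_set=frozenset(), soc_actionable=True).validate()
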