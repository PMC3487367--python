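import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from scampqi.cohort import Era
from scampqi.inference import (
    ProportionCI,
    Table2x2,
    binomial_ci,
    demographics_table,
    estimate_savings,
    fisher_exact_2x2,
    rank_sum_test,
    utilization_compare,
)
from scampqi.synth import generate_cohort, historical_default_spec, scamp_default_spec

from _oracles import fisher_oracle
from conftest import make_encounter


class TestFisherExact:
    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2(Table2x2(5, 5, 5, 5)) == 1.0

    def test_printed_contingency_below_1e4(self):
        p = fisher_exact_2x2(Table2x2(58, 93, 19, 122))
        assert p < 1e-4
        assert abs(p - fisher_oracle(58, 93, 19, 122)) < 1e-10

    @pytest.mark.parametrize("table", [(0, 0, 3, 4), (3, 0, 4, 0), (0, 3, 0, 4)])
    def test_zero_margin_degenerate(self, table):
        assert fisher_exact_2x2(Table2x2(*table)) == 1.0

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            Table2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            Table2x2(0, 0, 0, 0)

    def test_random_tables_match_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            a, b, c, d = (int(v) for v in rng.integers(0, 16, size=4))
            if a + b + c + d == 0:
                continue
            ours = fisher_exact_2x2(Table2x2(a, b, c, d))
            theirs = stats.fisher_exact([[a, b], [c, d]])[1]
            assert abs(ours - theirs) < 1e-10, (a, b, c, d)

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    @settings(max_examples=200, deadline=None)
    def test_transpose_and_swap_invariance(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_2x2(Table2x2(a, b, c, d))
        assert fisher_exact_2x2(Table2x2(a, c, b, d)) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_2x2(Table2x2(d, c, b, a)) == pytest.approx(p, abs=1e-12)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b, c, d = (int(v) for v in rng.integers(0, 31, size=4))
            if a + b + c + d == 0:
                continue
            p = fisher_exact_2x2(Table2x2(a, b, c, d))
            assert 0.0 < p <= 1.0


class TestBinomialCI:
    @pytest.mark.parametrize(
        "k,n,est,low,high",
        [
            (58, 151, 38.4, 30.7, 46.2),
            (19, 141, 13.5, 7.8, 19.1),
            (71, 255, 27.8, 22.3, 33.3),
        ],
    )
    def test_published_intervals(self, k, n, est, low, high):
        ci = binomial_ci(k, n)
        assert round(ci.estimate_pct, 1) == est
        assert round(ci.ci_low_pct, 1) == low
        assert round(ci.ci_high_pct, 1) == high

    def test_zero_successes_clipped(self):
        ci = binomial_ci(0, 20)
        assert ci.estimate_pct == 0.0
        assert ci.ci_low_pct == 0.0

    def test_full_successes_clipped(self):
        ci = binomial_ci(20, 20)
        assert ci.ci_high_pct == 100.0

    def test_n_zero_errors(self):
        with pytest.raises(ValueError):
            binomial_ci(0, 0)

    def test_k_bounds_enforced(self):
        with pytest.raises(ValueError):
            binomial_ci(5, 4)

    @given(st.integers(0, 500), st.integers(1, 500))
    @settings(max_examples=200, deadline=None)
    def test_ordering_invariant(self, k, n):
        if k > n:
            return
        ci = binomial_ci(k, n)
        assert 0.0 <= ci.ci_low_pct <= ci.estimate_pct <= ci.ci_high_pct <= 100.0


class TestRankSum:
    def test_identical_samples(self):
        assert rank_sum_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_exact_small_sample(self):
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(3, 9)))
            b = rng.normal(size=int(rng.integers(3, 9)))
            ours = rank_sum_test(a, b)
            theirs = stats.mannwhitneyu(a, b, method="exact", alternative="two-sided")[1]
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_large_sample_close_to_scipy_normal(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=120)
        b = rng.normal(0.3, size=140)
        ours = rank_sum_test(a, b)
        theirs = stats.mannwhitneyu(
            a, b, method="asymptotic", alternative="two-sided", use_continuity=True
        )[1]
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_type_i_error_rate(self):
        rng = np.random.default_rng(5)
        reps, n = 500, 200
        rejections = sum(
            rank_sum_test(rng.normal(size=n), rng.normal(size=n)) < 0.05
            for _ in range(reps)
        )
        assert 0.025 <= rejections / reps <= 0.075

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


def planted_cohorts(seed=0):
    hist = generate_cohort(historical_default_spec(seed=seed))
    scamp = generate_cohort(scamp_default_spec(seed=seed))
    return hist, scamp


class TestUtilizationCompare:
    def test_planted_est_difference(self, canonical_pair):
        hist, scamp = canonical_pair
        comparison = utilization_compare(hist, scamp)
        est = comparison.tests["est_done"]
        assert est.rate_historical.estimate_pct > est.rate_scamp.estimate_pct
        assert est.fisher_p < 0.001

    def test_identical_cohorts_all_p_one(self):
        cohort = [
            make_encounter(patient_id=str(i), echo_done=i % 3 == 0, est_done=i % 5 == 0)
            for i in range(60)
        ]
        comparison = utilization_compare(cohort, cohort)
        assert all(tu.fisher_p == 1.0 for tu in comparison.tests.values())

    def test_null_echo_rates_rarely_significant(self):
        # echo planted at the same marginal rate in both eras
        rejections = 0
        reps = 200
        for seed in range(reps):
            spec_h = dataclasses.replace(
                historical_default_spec(seed=seed),
                n=406,
                pattern_probs={0: 0.60, 1: 0.40},
            )
            spec_s = dataclasses.replace(
                scamp_default_spec(seed=seed + 10_000),
                n=364,
                pattern_probs={0: 0.60, 1: 0.40},
            )
            comparison = utilization_compare(
                generate_cohort(spec_h), generate_cohort(spec_s)
            )
            if comparison.tests["echo_done"].fisher_p <= 0.05:
                rejections += 1
        assert rejections / reps <= 0.10

    def test_frame_export_shape(self, canonical_pair):
        frame = utilization_compare(*canonical_pair).to_frame()
        assert len(frame) == 8
        assert set(frame.columns) == {
            "test",
            "era",
            "n_performed",
            "n_total",
            "rate_pct",
            "ci_low",
            "ci_high",
            "fisher_p",
        }


class TestDemographicsTable:
    def test_identical_cohorts_all_p_one(self):
        cohort_h = [
            make_encounter(
                patient_id=f"h{i}",
                era=Era.HISTORICAL,
                age_years=7.0 + (i % 14),
                palpitations=i % 4 == 0,
                exertional_pain=i % 3 == 0,
            )
            for i in range(50)
        ]
        cohort_s = [
            dataclasses.replace(e, era=Era.SCAMP, patient_id=f"s{i}")
            for i, e in enumerate(cohort_h)
        ]
        table = demographics_table(cohort_h, cohort_s)
        for row in table.rows:
            if row.p_value is not None:
                assert row.p_value == pytest.approx(1.0)

    def test_male_percent_display(self):
        cohort_h = [
            make_encounter(
                patient_id=f"h{i}",
                era=Era.HISTORICAL,
                sex="male" if i < 207 else "female",
            )
            for i in range(406)
        ]
        cohort_s = [
            make_encounter(
                patient_id=f"s{i}", sex="male" if i < 187 else "female"
            )
            for i in range(364)
        ]
        table = demographics_table(cohort_h, cohort_s)
        male_row = table.rows[0]
        assert male_row.historical == "207 (51%)"
        assert male_row.scamp == "187 (51%)"

    def test_planted_palpitations_difference_detected(self):
        rejections = 0
        reps = 200
        for seed in range(reps):
            hist = generate_cohort(
                dataclasses.replace(historical_default_spec(seed=seed), n=406)
            )
            scamp = generate_cohort(
                dataclasses.replace(scamp_default_spec(seed=seed + 50_000), n=364)
            )
            table = demographics_table(hist, scamp)
            palp = next(r for r in table.rows if "palpitations" in r.label.lower())
            if palp.p_value < 0.05:
                rejections += 1
        assert rejections / reps >= 0.80

    def test_row_layout(self, canonical_pair):
        table = demographics_table(*canonical_pair)
        labels = [r.label for r in table.rows]
        assert labels[0] == "Male (n, %)"
        assert sum("Age" in lab for lab in labels) == 4
        assert len(table.to_frame()) == len(labels)


class TestEstimateSavings:
    def make_comparison(self, rate_h, rate_s, n_scamp=364):
        from scampqi.inference import TestUtilization, UtilizationComparison

        ci_h = binomial_ci(int(rate_h * 1000), 1000)
        ci_s = binomial_ci(int(rate_s * 1000), 1000)
        tu = TestUtilization(
            test="exercise stress test",
            rate_historical=ci_h,
            rate_scamp=ci_s,
            fisher_p=0.5,
        )
        return UtilizationComparison(
            n_historical=406, n_scamp=n_scamp, tests={"est_done": tu}
        )

    def test_zero_difference_zero_savings(self):
        comparison = self.make_comparison(0.1, 0.1)
        assert estimate_savings(comparison, {"est_done": 500.0}, 0.6) == 0.0

    def test_worked_example(self):
        comparison = self.make_comparison(0.29, 0.033)
        savings = estimate_savings(comparison, {"est_done": 1000.0}, 0.6)
        assert savings == pytest.approx((0.29 - 0.033) * 364 * 1000 * 0.6)

    def test_linear_in_ratio_and_charge(self):
        comparison = self.make_comparison(0.29, 0.033)
        s1 = estimate_savings(comparison, {"est_done": 1000.0}, 0.3)
        s2 = estimate_savings(comparison, {"est_done": 1000.0}, 0.6)
        s3 = estimate_savings(comparison, {"est_done": 2000.0}, 0.3)
        assert s2 == pytest.approx(2 * s1)
        assert s3 == pytest.approx(2 * s1)

    def test_missing_charge_errors(self):
        comparison = self.make_comparison(0.29, 0.033)
        with pytest.raises(KeyError):
            estimate_savings(comparison, {}, 0.6)

    def test_bad_ratio_errors(self):
        comparison = self.make_comparison(0.29, 0.033)
        with pytest.raises(ValueError):
            estimate_savings(comparison, {"est_done": 100.0}, 0.0)
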