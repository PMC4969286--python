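"""MEP after-effect statistics and the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tesplan.mep import (
    POST_INTERVALS_MIN,
    CohortSpec,
    ParticipantSession,
    analyze_cohort,
    analyze_session,
    cohort_tests,
    exact_binomial_tail,
    normalize_to_baseline,
    paired_one_tailed_t,
    simulate_cohort,
    trimmed_mep_mean,
)


class TestTrimmedMean:
    def test_sequence_one_to_twelve(self):
        assert trimmed_mep_mean(np.arange(1.0, 13.0)) == 6.5

    def test_constant_block(self):
        assert trimmed_mep_mean(np.full(12, 0.8)) == pytest.approx(0.8)

    @given(st.lists(st.floats(0.0, 10.0), min_size=3, max_size=20))
    def test_matches_sort_and_slice_oracle(self, amps):
        got = trimmed_mep_mean(np.array(amps))
        oracle = float(np.mean(np.sort(amps)[1:-1]))
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="3 trials"):
            trimmed_mep_mean(np.array([1.0, 2.0]))


class TestNormalization:
    def test_unchanged_amplitudes_give_unit_ratios(self):
        ratios = normalize_to_baseline(1.3, {t: 1.3 for t in POST_INTERVALS_MIN})
        assert all(r == pytest.approx(1.0) for r in ratios.values())

    def test_ratio_definition(self):
        assert normalize_to_baseline(1.0, {0: 0.79})[0] == pytest.approx(0.79)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            normalize_to_baseline(0.0, {0: 1.0})

    def test_interval_groupings(self):
        means = {t: 1.0 for t in POST_INTERVALS_MIN}
        means[60], means[90] = 0.6, 0.8
        s = ParticipantSession(0, "cathodal", 1.0, means)
        assert s.grouped_ratio("60-90") == pytest.approx(0.7)
        assert s.grouped_ratio("0-30") == pytest.approx(1.0)
        assert s.overall_ratio == pytest.approx((7 * 1.0 + 0.6 + 0.8) / 9)


class TestPairedT:
    def test_identical_vectors(self):
        r = paired_one_tailed_t(np.ones(6), np.ones(6))
        assert r.degenerate and r.p == 0.5 and r.t == 0.0

    def test_consistent_negative_shift_is_significant(self):
        rng = np.random.default_rng(0)
        x = np.zeros(4) + rng.normal(0, 1e-6, 4)
        y = x + 1.0  # differences ~ -1 with tiny jitter
        r = paired_one_tailed_t(y - 1.0, y)
        assert r.p < 0.005

    def test_matches_scipy_reference(self, rng):
        for _ in range(100):
            n = rng.integers(3, 30)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            ours = paired_one_tailed_t(x, y)
            ref = stats.ttest_rel(x, y, alternative="less")
            assert ours.t == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_type_one_error_rate_under_null(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 10_000
        for _ in range(reps):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            if paired_one_tailed_t(x, y).p < 0.05:
                rejections += 1
        assert 0.04 <= rejections / reps <= 0.06

    def test_zero_variance_flagged(self):
        r = paired_one_tailed_t(np.array([1.0, 1.0, 1.0]), np.array([2.0, 2.0, 2.0]))
        assert r.degenerate and r.p == 0.0


class TestExactBinomial:
    def test_certain_success_limit(self):
        assert exact_binomial_tail(12, 12, 1 - 1e-12) == pytest.approx(1.0)

    def test_cathodal_response_proportion(self):
        p = exact_binomial_tail(10, 12, 22 / 53)
        assert p == pytest.approx(0.0039, abs=2e-4)
        assert p < 0.01

    def test_anodal_response_proportion(self):
        assert exact_binomial_tail(8, 12, 0.26) < 0.004

    @given(st.integers(0, 20), st.integers(0, 20), st.floats(0.01, 0.99))
    def test_complementary_tails_sum_to_one(self, k, n, p0):
        if k > n or n == 0:
            return
        upper = exact_binomial_tail(k, n, p0)
        lower = exact_binomial_tail(k - 1, n, p0, tail="lower") if k > 0 else 0.0
        assert upper + lower == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_survival_function(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.uniform(0.05, 0.95))
            assert exact_binomial_tail(k, n, p0) == pytest.approx(
                stats.binom.sf(k - 1, n, p0), rel=1e-10
            )


class TestCohortGenerator:
    def test_deterministic_under_fixed_seed(self):
        a = simulate_cohort(CohortSpec(n_participants=4, seed=11))
        b = simulate_cohort(CohortSpec(n_participants=4, seed=11))
        pd.testing.assert_frame_equal(a, b)

    def test_block_sizes(self):
        trials = simulate_cohort(CohortSpec(n_participants=3, seed=0))
        counts = trials.groupby(["participant", "condition", "interval"]).size()
        assert set(counts[counts.index.get_level_values("interval") == "baseline"]) == {10}
        assert set(counts[counts.index.get_level_values("interval") != "baseline"]) == {12}

    def test_cathodal_mean_recovered_at_n500(self):
        trials = simulate_cohort(CohortSpec(n_participants=500, seed=9))
        ratios = analyze_cohort(trials)
        assert ratios["cathodal"].mean() == pytest.approx(0.79, abs=0.02)

    def test_power_for_cathodal_contrast(self):
        # under the generator's effect sizes a 12-participant crossover
        # rejects cathodal-vs-placebo at alpha=0.05 in the majority of runs
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            trials = simulate_cohort(CohortSpec(n_participants=12, seed=seed))
            res = cohort_tests(analyze_cohort(trials))["cathodal"]
            if res.p < 0.05:
                rejections += 1
        assert rejections > n_seeds / 2

    def test_exclusion_flag(self):
        trials = simulate_cohort(CohortSpec(n_participants=5, seed=2))
        full = analyze_cohort(trials)
        dropped = analyze_cohort(trials, exclude_participants=(3,))
        assert 3 in full.index and 3 not in dropped.index
        assert len(dropped) == len(full) - 1

    def test_session_missing_block_rejected(self):
        trials = simulate_cohort(CohortSpec(n_participants=2, seed=0))
        one = trials[(trials.participant == 0) & (trials.condition == "anodal")]
        broken = one[one.interval != "60"]
        with pytest.raises(ValueError, match="60-minute"):
            analyze_session(broken)
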