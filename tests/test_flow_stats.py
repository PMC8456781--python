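"""Activity indices, ΔΔCt, randomization/bootstrap statistics, Tukey summaries."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from filotip import (
    CtTable,
    activity_index_9eg7,
    activity_index_fn,
    effect_size,
    randomization_test,
    rectangular_gate,
    relative_expression_ddct,
    tukey_summary,
)
from filotip.errors import ArgumentError


class TestActivityIndices:
    def test_fn_index_edta_baseline(self):
        assert activity_index_fn(100.0, 100.0, 400.0) == 0.0

    def test_fn_index_arithmetic(self):
        assert activity_index_fn(300.0, 100.0, 400.0) == 0.5

    def test_fn_index_gain_invariance(self):
        base = activity_index_fn(300.0, 100.0, 400.0)
        assert activity_index_fn(600.0, 200.0, 800.0) == pytest.approx(base)

    def test_fn_index_requires_positive_total(self):
        with pytest.raises(ArgumentError):
            activity_index_fn(300.0, 100.0, 0.0)

    def test_9eg7_index_limits(self):
        assert activity_index_9eg7(100.0, 1700.0, 100.0) == 0.0
        assert activity_index_9eg7(1700.0, 1700.0, 100.0) == 1.0
        assert activity_index_9eg7(900.0, 1700.0, 100.0) == 0.5

    def test_9eg7_background_above_total_raises(self):
        with pytest.raises(ArgumentError):
            activity_index_9eg7(900.0, 100.0, 200.0)

    def test_gain_invariance_9eg7(self):
        a = activity_index_9eg7(900.0, 1700.0, 100.0)
        b = activity_index_9eg7(1800.0, 3400.0, 200.0)
        assert a == pytest.approx(b)


def _ct_table(rows):
    return CtTable(pd.DataFrame(rows, columns=["gene", "sample", "ct"]))


class TestDdct:
    def test_all_equal_is_unity(self):
        ct = _ct_table(
            [("g", "s", 20.0), ("GAPDH", "s", 20.0), ("g", "c", 20.0), ("GAPDH", "c", 20.0)]
        )
        assert relative_expression_ddct(ct, "g", "s", "c") == 1.0

    def test_one_cycle_earlier_doubles(self):
        ct = _ct_table(
            [("g", "s", 19.0), ("GAPDH", "s", 20.0), ("g", "c", 20.0), ("GAPDH", "c", 20.0)]
        )
        assert relative_expression_ddct(ct, "g", "s", "c") == 2.0

    def test_worked_arithmetic(self):
        ct = _ct_table(
            [("g", "s", 24.0), ("GAPDH", "s", 18.0), ("g", "c", 26.0), ("GAPDH", "c", 18.0)]
        )
        assert relative_expression_ddct(ct, "g", "s", "c") == 4.0

    def test_constant_ct_shift_cancels(self):
        base = _ct_table(
            [("g", "s", 24.0), ("GAPDH", "s", 18.0), ("g", "c", 26.0), ("GAPDH", "c", 18.0)]
        )
        shifted = _ct_table(
            [("g", "s", 27.0), ("GAPDH", "s", 21.0), ("g", "c", 29.0), ("GAPDH", "c", 21.0)]
        )
        assert relative_expression_ddct(base, "g", "s", "c") == relative_expression_ddct(
            shifted, "g", "s", "c"
        )

    def test_missing_ct_names_the_cell(self):
        ct = _ct_table([("g", "s", 24.0), ("GAPDH", "s", 18.0)])
        with pytest.raises(ArgumentError, match="control"):
            relative_expression_ddct(ct, "g", "s", "control")


def _exact_perm_p(a, b):
    """Independent exhaustive-enumeration oracle for the mean-difference test."""
    pooled = np.concatenate([a, b])
    obs = abs(np.mean(a) - np.mean(b))
    count = total = 0
    for idx in combinations(range(pooled.size), len(a)):
        mask = np.zeros(pooled.size, bool)
        mask[list(idx)] = True
        count += abs(pooled[mask].mean() - pooled[~mask].mean()) >= obs - 1e-12
        total += 1
    return count / total


class TestRandomizationTest:
    def test_identical_groups_give_p_one(self):
        a = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert randomization_test(a, a.copy(), n_resamples=299, seed=0) == 1.0

    def test_exact_mode_matches_enumeration_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([101.0, 102.0, 103.0])
        oracle = _exact_perm_p(a, b)
        assert oracle == 2 / 20
        assert randomization_test(a, b, exact=True) == oracle

    def test_monte_carlo_converges_to_exact(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([101.0, 102.0, 103.0])
        p = randomization_test(a, b, n_resamples=20000, seed=3)
        assert p == pytest.approx(2 / 20, abs=0.01)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_mode_matches_oracle_on_random_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 5), rng.normal(0.5, 1, 5)
        assert randomization_test(a, b, exact=True) == pytest.approx(
            _exact_perm_p(a, b), abs=1e-12
        )

    def test_median_statistic_supported(self):
        a, b = np.array([1.0, 2.0, 30.0]), np.array([1.1, 2.1, 31.0])
        p = randomization_test(a, b, n_resamples=199, statistic="median", seed=0)
        assert 0 < p <= 1

    def test_bad_resamples_raises(self):
        with pytest.raises(ArgumentError):
            randomization_test([1.0, 2.0], [3.0, 4.0], n_resamples=0)


class TestEffectSize:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        diff, ci = effect_size(a, a.copy(), n_boot=200, seed=0)
        assert diff == 0.0
        assert ci[0] <= 0.0 <= ci[1]

    def test_constant_groups_degenerate_ci(self):
        diff, ci = effect_size(np.full(5, 5.0), np.full(5, 3.0), n_boot=100, seed=0)
        assert diff == 2.0
        assert ci == (2.0, 2.0)

    def test_coverage_on_normal_groups(self, rng):
        # moderate-n check of nominal CI coverage
        covered = 0
        n_sim = 100
        for _ in range(n_sim):
            a = rng.normal(1.0, 1.0, 60)
            b = rng.normal(0.0, 1.0, 60)
            _, (lo, hi) = effect_size(a, b, n_boot=300, seed=int(rng.integers(2**31)))
            covered += lo <= 1.0 <= hi
        se = np.sqrt(0.95 * 0.05 / n_sim)
        assert abs(covered / n_sim - 0.95) < 3 * se + 0.01


class TestTukeySummary:
    def test_seven_point_sample_type7_quartiles(self):
        s = tukey_summary(np.arange(1.0, 8.0))
        # linear-interpolation (type-7) quartiles, computed with np.percentile
        assert (s.median, s.q1, s.q3) == (4.0, 2.5, 5.5)
        assert s.outliers.size == 0
        assert (s.whisker_low, s.whisker_high) == (1.0, 7.0)

    def test_single_value(self):
        s = tukey_summary([42.0])
        assert s.median == s.q1 == s.q3 == s.whisker_low == s.whisker_high == 42.0

    def test_far_point_is_outlier_and_whisker_unchanged(self):
        base = np.arange(1.0, 8.0)
        s0 = tukey_summary(base)
        far = s0.q3 + 10 * (s0.q3 - s0.q1)
        s1 = tukey_summary(np.append(base, far))
        assert far in s1.outliers
        assert s1.whisker_high == s0.whisker_high


class TestGate:
    def test_rectangular_gate_filters_rows(self):
        df = pd.DataFrame({"F": [1.0, 5.0, 9.0], "S": [2.0, 2.0, 2.0]})
        out = rectangular_gate(df, {"F": (2.0, 8.0)})
        assert list(out["F"]) == [5.0]

    def test_missing_channel_raises(self):
        with pytest.raises(ArgumentError):
            rectangular_gate(pd.DataFrame({"F": [1.0]}), {"X": (0, 1)})


class TestScaleInvariances:
    @given(st.floats(0.1, 100.0))
    def test_fn_index_degree_zero_homogeneity(self, gain):
        base = activity_index_fn(300.0, 100.0, 400.0)
        scaled = activity_index_fn(300.0 * gain, 100.0 * gain, 400.0 * gain)
        assert scaled == pytest.approx(base, rel=1e-9)
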