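"""Unit tests of the robust two-sample estimators against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import betainc

from dimorph.effects import (
    DECILES,
    BootstrapConfig,
    bootstrap_moment_difference,
    classify_magnitude,
    cliff_delta_inference,
    cohens_u3_empirical,
    decile_shift_test,
    fdr_adjust,
    global_wmw_test,
    hd_quantile,
    hd_quantiles,
    iqr_ratio_test,
    overlap_eta,
)


def hd_oracle(x, q):
    """Direct incomplete-beta summation over order statistics."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    a, b = (n + 1) * q, (n + 1) * (1 - q)
    total = 0.0
    for i in range(1, n + 1):
        w = betainc(a, b, i / n) - betainc(a, b, (i - 1) / n)
        total += w * x[i - 1]
    return total


def cliff_oracle(x_a, x_b):
    """Exhaustive O(n^2) pair counting."""
    gt = sum(1 for a in x_a for b in x_b if a > b)
    lt = sum(1 for a in x_a for b in x_b if a < b)
    n = len(x_a) * len(x_b)
    return (gt - lt) / n, (gt + 0.5 * (n - gt - lt)) / n


class TestHarrellDavis:
    def test_symmetric_median(self):
        assert hd_quantile([1, 2, 3], 0.5) == pytest.approx(2.0, abs=1e-12)

    def test_constant_sample(self):
        for q in (0.1, 0.5, 0.9):
            assert hd_quantile([4.2] * 7, q) == pytest.approx(4.2, abs=1e-12)

    @pytest.mark.parametrize("n,q", [(10, 0.1), (10, 0.5), (25, 0.3), (50, 0.9), (7, 0.25)])
    def test_matches_beta_summation_oracle(self, n, q, rng):
        x = rng.normal(size=n)
        assert hd_quantile(x, q) == pytest.approx(hd_oracle(x, q), abs=1e-12)

    def test_weights_sum_to_one_and_monotone_in_q(self, rng):
        x = rng.normal(size=31)
        qs = np.linspace(0.05, 0.95, 19)
        vals = hd_quantiles(x, qs)
        assert np.all(np.diff(vals) >= -1e-12)
        # constant input maps to that constant iff weights sum to 1
        ones = hd_quantiles(np.ones(31), qs)
        assert np.allclose(ones, 1.0, atol=1e-12)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            hd_quantile([], 0.5)
        with pytest.raises(ValueError):
            hd_quantile([1, 2], 1.5)


class TestCliffDelta:
    def test_hand_example(self):
        res = cliff_delta_inference([1, 2, 3], [0, 0, 4])
        assert res.delta.value == pytest.approx(1 / 3, abs=1e-15)
        assert res.ps_a == pytest.approx(2 / 3, abs=1e-15)

    def test_identical_samples_null(self, rng):
        x = rng.normal(size=40)
        res = cliff_delta_inference(x, x)
        assert res.delta.value == 0.0
        assert res.ps_a == pytest.approx(0.5)

    def test_complete_separation(self):
        res = cliff_delta_inference([10, 11, 12], [1, 2, 3])
        assert res.delta.value == 1.0
        assert res.ps_a == 1.0

    @pytest.mark.parametrize("na,nb", [(5, 7), (20, 20), (50, 31), (200, 150)])
    def test_matches_exhaustive_counting(self, na, nb, rng):
        a = rng.normal(size=na)
        b = np.round(rng.normal(size=nb), 1)  # induce ties occasionally
        d_oracle, ps_oracle = cliff_oracle(list(a), list(b))
        res = cliff_delta_inference(a, b)
        assert res.delta.value == pytest.approx(d_oracle, abs=1e-12)
        assert res.ps_a == pytest.approx(ps_oracle, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(-5, 5), min_size=2, max_size=15),
           st.lists(st.integers(-5, 5), min_size=2, max_size=15))
    def test_properties(self, xs, ys):
        res = cliff_delta_inference(xs, ys)
        swapped = cliff_delta_inference(ys, xs)
        assert -1.0 <= res.delta.value <= 1.0
        # delta = 2 PS - 1 under the half-tie convention; antisymmetry under swap
        assert res.delta.value == pytest.approx(2 * res.ps_a - 1, abs=1e-12)
        assert swapped.delta.value == pytest.approx(-res.delta.value, abs=1e-12)
        assert res.ps_a + res.ps_b == pytest.approx(1.0, abs=1e-12)

    def test_ci_brackets_value(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=60) + 0.4
        d = cliff_delta_inference(a, b).delta
        assert d.ci_low <= d.value <= d.ci_high
        assert -1.0 <= d.ci_low and d.ci_high <= 1.0


class TestDecileShift:
    def test_point_estimates_equal_direct_hd_differences(self, fast_cfg, rng):
        a, b = rng.normal(size=60), rng.normal(size=55) + 0.3
        res = decile_shift_test(a, b, fast_cfg)
        direct = hd_quantiles(a, DECILES) - hd_quantiles(b, DECILES)
        assert np.allclose(res.difference, direct, atol=1e-12)

    def test_same_sample_gives_zero(self, fast_cfg, rng):
        x = rng.normal(size=50)
        res = decile_shift_test(x, x, fast_cfg)
        assert np.allclose(res.difference, 0.0, atol=1e-12)

    def test_location_shift_recovered(self, fast_cfg, rng):
        x = rng.normal(size=500)
        res = decile_shift_test(x, x + 1.0, fast_cfg)
        assert np.allclose(res.difference, -1.0, atol=0.15)
        assert res.significant.all()

    def test_small_group_rejected(self, fast_cfg):
        with pytest.raises(ValueError):
            decile_shift_test([1.0] * 5, [2.0] * 30, fast_cfg)


class TestGlobalTest:
    def test_same_sample_zero_shift(self, fast_cfg, rng):
        x = rng.normal(size=40)
        res = global_wmw_test(x, x, fast_cfg)
        assert res["shift"].value == pytest.approx(0.0, abs=1e-12)

    def test_large_shift_detected(self, fast_cfg, rng):
        x = rng.normal(size=500)
        res = global_wmw_test(x, x + 1.0, fast_cfg)
        assert res["p"] < 1e-3
        assert res["shift"].value == pytest.approx(-1.0, abs=0.2)

    def test_brunner_munzel_alternative(self, fast_cfg, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = global_wmw_test(x, y, fast_cfg, method="brunner-munzel")
        assert 0.0 <= res["p"] <= 1.0


class TestOverlap:
    def test_same_sample_full_overlap(self, fast_cfg, rng):
        x = rng.normal(size=100)
        assert overlap_eta(x, x, fast_cfg).value >= 0.99

    def test_disjoint_samples_no_overlap(self, fast_cfg, rng):
        a = rng.normal(size=100)
        assert overlap_eta(a, a + 100.0, fast_cfg).value <= 0.01

    @pytest.mark.parametrize("delta", [0.5, 1.0, 2.0])
    def test_gaussian_closed_form(self, fast_cfg, delta, rng):
        a = rng.normal(size=2000)
        b = rng.normal(size=2000) + delta
        eta = overlap_eta(a, b, fast_cfg).value
        assert eta == pytest.approx(2 * stats.norm.cdf(-delta / 2), abs=0.03)

    def test_degenerate_group_rejected(self, fast_cfg):
        with pytest.raises(ValueError):
            overlap_eta([1.0] * 20, [1.0, 2.0] * 10, fast_cfg)


class TestU3:
    def test_direct_count_example(self, fast_cfg):
        # median of B is 2.5, so exactly 2 of 4 A values lie strictly above
        res = cohens_u3_empirical([1, 2, 3, 4], [2, 3], fast_cfg)
        assert res.value == pytest.approx(50.0)

    def test_total_dominance(self, fast_cfg, rng):
        a = rng.normal(size=30) + 100
        b = rng.normal(size=30)
        assert cohens_u3_empirical(a, b, fast_cfg).value == 100.0

    def test_identical_distributions_near_half(self, fast_cfg, rng):
        a, b = rng.normal(size=2000), rng.normal(size=2000)
        assert cohens_u3_empirical(a, b, fast_cfg).value == pytest.approx(50.0, abs=5.0)


class TestIqrRatio:
    def test_same_sample_ratio_one(self, fast_cfg, rng):
        x = rng.normal(size=80)
        res = iqr_ratio_test(x, x, fast_cfg)
        assert res.value == pytest.approx(1.0, abs=1e-12)
        assert res.p > 0.5

    def test_scale_doubling_flagged(self, fast_cfg, rng):
        x = rng.normal(size=500)
        res = iqr_ratio_test(x, 2 * x, fast_cfg)
        assert res.value == pytest.approx(0.5, abs=0.05)
        assert res.p < 0.01


class TestMomentDifference:
    def test_mirrored_skewness_antisymmetry(self, fast_cfg, rng):
        x = rng.gamma(2.0, size=200)
        res = bootstrap_moment_difference(x, -x, "skewness", fast_cfg)
        assert res.value == pytest.approx(2 * stats.skew(x), abs=1e-12)

    def test_gaussian_kurtosis_near_three(self, fast_cfg, rng):
        a, b = rng.normal(size=500), rng.normal(size=500)
        res = bootstrap_moment_difference(a, b, "kurtosis", fast_cfg)
        # non-excess convention: each group's plug-in kurtosis is close to 3
        assert stats.kurtosis(a, fisher=False) == pytest.approx(3.0, abs=0.6)
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_unknown_moment_rejected(self, fast_cfg, rng):
        with pytest.raises(ValueError):
            bootstrap_moment_difference(rng.normal(size=30), rng.normal(size=30), "variance", fast_cfg)


class TestFdrAndBenchmarks:
    def test_bh_hand_example(self):
        out = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_tied_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(fdr_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=25)
        assert np.all(fdr_adjust(p) >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @pytest.mark.parametrize(
        "value,index,expected",
        [
            (0.62, "cliff_delta", "large"),
            (0.22, "cliff_delta", "small"),
            (0.474, "cliff_delta", "large"),
            (0.80, "cohen_d", "large"),
            (0.35, "cohen_d", "small"),
            (0.0, "cohen_d", "negligible"),
            (-0.6, "cohen_d", "medium"),
        ],
    )
    def test_benchmark_labels(self, value, index, expected):
        assert classify_magnitude(value, index) == expected

    def test_unknown_index_rejected(self):
        with pytest.raises(ValueError):
            classify_magnitude(0.5, "eta_squared")


class TestReproducibility:
    def test_bootstrap_operations_deterministic_under_seed(self, rng):
        a, b = rng.normal(size=60), rng.normal(size=60) + 0.2
        cfg = BootstrapConfig(n_boot_deciles=150, n_boot_overlap=80, n_boot_u3=80,
                              n_boot_moments=80, seed=99)
        r1 = decile_shift_test(a, b, cfg)
        r2 = decile_shift_test(a, b, cfg)
        assert np.array_equal(r1.ci_low, r2.ci_low)
        e1 = overlap_eta(a, b, cfg)
        e2 = overlap_eta(a, b, cfg)
        assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)
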