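"""Permutation statistics: construction oracles, invariances, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vertisource.stats import (
    ParameterError,
    pearson_with_p,
    roi_band_anova,
    snpm_group_compare,
    voxelwise_correlation,
)


class TestGroupCompare:
    def test_planted_voxel_detected_others_not(self, rng):
        n, V = 12, 60
        for seed in range(3):
            r = np.random.default_rng(seed)
            A = r.standard_normal((n, V))
            B = r.standard_normal((n, V))
            A[:, 17] += 5.0  # 5 pooled-SD shift
            sm = snpm_group_compare(A, B, n_perm=1000, seed=seed)
            assert sm.significant[17]
            assert sm.significant.sum() == 1

    def test_label_swap_negates_t_same_significant_set(self, rng):
        A = rng.standard_normal((8, 40))
        B = rng.standard_normal((8, 40)) + 0.8
        sm1 = snpm_group_compare(A, B, n_perm=500, seed=3)
        sm2 = snpm_group_compare(B, A, n_perm=500, seed=3)
        assert np.allclose(sm1.stat, -sm2.stat)
        assert np.array_equal(sm1.significant, sm2.significant)

    def test_seed_reproducibility(self, rng):
        A, B = rng.standard_normal((6, 30)), rng.standard_normal((6, 30))
        a = snpm_group_compare(A, B, n_perm=300, seed=5)
        b = snpm_group_compare(A, B, n_perm=300, seed=5)
        assert np.array_equal(a.max_null, b.max_null)

    def test_corrected_subset_of_uncorrected(self, rng):
        A = rng.standard_normal((10, 80))
        B = rng.standard_normal((10, 80)) + 0.7
        sm = snpm_group_compare(A, B, n_perm=800, seed=1)
        t_crit = sps.t.ppf(1 - 0.025, df=18)
        uncorrected = np.abs(sm.stat) >= t_crit
        assert np.all(uncorrected[sm.significant])

    def test_constant_voxel_flagged_nan(self, rng):
        A = rng.standard_normal((5, 10))
        B = rng.standard_normal((5, 10))
        A[:, 2] = B[:, 2] = 1.0
        sm = snpm_group_compare(A, B, n_perm=200, seed=0)
        assert np.isnan(sm.stat[2]) and not sm.significant[2]

    def test_small_n_perm_warns(self, rng):
        with pytest.warns(UserWarning):
            snpm_group_compare(rng.standard_normal((4, 5)),
                               rng.standard_normal((4, 5)), n_perm=50, seed=0)


class TestVoxelwiseCorrelation:
    def test_behavior_built_from_voxel_is_found(self, rng):
        maps = rng.standard_normal((20, 50))
        behavior = maps[:, 31] + 0.1 * rng.standard_normal(20)
        sm = voxelwise_correlation(maps, behavior, n_perm=1000, seed=2)
        assert sm.significant[31] and sm.stat[31] > 0.9

    def test_negated_behavior_negates_r(self, rng):
        maps = rng.standard_normal((15, 30))
        b = rng.standard_normal(15)
        s1 = voxelwise_correlation(maps, b, n_perm=300, seed=4)
        s2 = voxelwise_correlation(maps, -b, n_perm=300, seed=4)
        assert np.allclose(s1.stat, -s2.stat, atol=1e-12)

    def test_constant_behavior_rejected(self, rng):
        with pytest.raises(ParameterError):
            voxelwise_correlation(rng.standard_normal((8, 5)), np.ones(8))


class TestAnova:
    def test_three_sd_effect_is_extreme(self, rng):
        a = rng.standard_normal(12)
        b = rng.standard_normal(12) + 3.0
        values = pd.DataFrame({"roi": np.concatenate([a, b])})
        res = roi_band_anova(values, np.array(["A"] * 12 + ["B"] * 12))
        # analytic power check: noncentral F with lambda = n/2 * d^2 makes
        # p < .001 overwhelmingly likely at d = 3, n = 12 + 12
        assert res.loc["roi", "p"] < 0.001

    def test_f_matches_squared_t(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(10)
        res = roi_band_anova(pd.DataFrame({"x": np.r_[a, b]}),
                             np.array(["A"] * 10 + ["B"] * 10))
        t = sps.ttest_ind(a, b)
        assert res.loc["x", "F"] == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.loc["x", "p"] == pytest.approx(t.pvalue, rel=1e-9)

    def test_within_group_order_invariance(self, rng):
        vals = rng.standard_normal(16)
        g = np.array(["A"] * 8 + ["B"] * 8)
        df1 = pd.DataFrame({"x": vals})
        shuffled = np.r_[np.random.default_rng(0).permutation(vals[:8]),
                         np.random.default_rng(1).permutation(vals[8:])]
        df2 = pd.DataFrame({"x": shuffled})
        r1 = roi_band_anova(df1, g)
        r2 = roi_band_anova(df2, g)
        assert r1.loc["x", "F"] == pytest.approx(r2.loc["x", "F"], rel=1e-12)

    def test_degenerate_variance_raises(self):
        df = pd.DataFrame({"x": np.r_[np.ones(5), np.full(5, 2.0)]})
        with pytest.raises(ParameterError):
            roi_band_anova(df, np.array(["A"] * 5 + ["B"] * 5))


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        a = rng.standard_normal(20)
        r, p = pearson_with_p(a, a)
        assert r == pytest.approx(1.0)

    def test_orthogonal_contrasts_are_uncorrelated(self):
        r, _ = pearson_with_p([1, -1, 1, -1], [1, 1, -1, -1])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_null_rejection_rate_calibrated(self):
        """Independent Gaussian pairs, n=23: p<.05 rate within 3.5-6.5%."""
        r = np.random.default_rng(99)
        hits = 0
        for _ in range(1000):
            _, p = pearson_with_p(r.standard_normal(23), r.standard_normal(23))
            hits += p < 0.05
        assert 35 <= hits <= 65

    def test_constant_rejected(self):
        with pytest.raises(ParameterError):
            pearson_with_p(np.ones(5), np.arange(5))


def test_doubling_permutations_keeps_threshold_stable(rng):
    """Threshold shift stays within the null's Monte-Carlo error."""
    A, B = rng.standard_normal((10, 100)), rng.standard_normal((10, 100))
    t1 = snpm_group_compare(A, B, n_perm=2000, seed=0).threshold
    t2 = snpm_group_compare(A, B, n_perm=4000, seed=1).threshold
    assert abs(t1 - t2) < 0.25
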