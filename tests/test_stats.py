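"""Offline statistics: sign test, descriptives, permutation slope test,
activation baselines, Jarque-Bera."""

import numpy as np
import pytest
import scipy.stats

from rtdcm.stats import (cnr, describe, differential_feedback, jarque_bera,
                         percent_signal_change, permutation_slope_test,
                         sign_test)


class TestSignTest:
    @pytest.mark.parametrize("k,n,z2dp", [
        (97, 168, 1.93), (53, 84, 2.29), (44, 84, 0.33),
        (32, 56, 0.94), (29, 56, 0.13), (36, 56, 2.00),
    ])
    def test_continuity_corrected_z(self, k, n, z2dp):
        assert sign_test(k=k, n=n).z == pytest.approx(z2dp, abs=0.005)

    def test_p_from_unrounded_z(self):
        # (97/168): z rounds to 1.93 but p comes from the exact z
        assert sign_test(k=97, n=168).p == pytest.approx(0.027, abs=5e-4)
        assert sign_test(k=32, n=56).p == pytest.approx(0.175, abs=5e-4)

    def test_counts_from_values_exclude_zeros(self):
        res = sign_test([1.0, 2.0, -1.0, 0.0, 0.0, 3.0])
        assert (res.k, res.n) == (3, 4)

    def test_normal_approx_close_to_exact_binomial(self):
        # k=8, n=10: exact one-tailed p = sum_{j>=8} C(10,j)/2^10 = 56/1024
        from math import comb
        p_exact = sum(comb(10, j) for j in range(8, 11)) / 2 ** 10
        assert p_exact == 56 / 1024
        assert abs(sign_test(k=8, n=10).p - p_exact) < 0.02

    def test_normal_approx_converges_for_large_n(self):
        from math import comb
        n, k = 500, 275  # k/n = 0.55
        p_exact = sum(comb(n, j) for j in range(k, n + 1)) / 2.0 ** n
        assert abs(sign_test(k=k, n=n).p - p_exact) < 0.005

    def test_z_monotone_in_k(self):
        zs = [sign_test(k=k, n=30).z for k in range(31)]
        assert np.all(np.diff(zs) > 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sign_test([0.0, 0.0])


class TestDescribe:
    def test_median_of_small_sample(self):
        assert describe([1, 2, 3, 4, 5]).m == 3.0

    def test_constant_sample_has_zero_iqr(self):
        d = describe([2.0] * 10)
        assert d.iqr == 0.0
        assert d.fq == d.m == d.sq == 2.0

    def test_standard_normal_quartiles(self):
        rng = np.random.default_rng(0)
        d = describe(rng.standard_normal(10_000))
        assert abs(d.m) < 0.05
        assert abs(d.iqr - 1.349) < 0.05

    def test_invariant_ordering(self):
        rng = np.random.default_rng(1)
        d = describe(rng.standard_normal(101))
        assert d.fq <= d.m <= d.fq + d.iqr


class TestPermutationSlope:
    def test_minimum_p_is_one_over_nperm_plus_one(self):
        v = np.concatenate([np.zeros(10) - 5, np.zeros(10), np.zeros(10) + 5])
        labels = np.repeat([0, 1, 2], 10)
        p = permutation_slope_test(v, labels, n_perm=999, seed=0)
        assert p >= 1 / 1000
        assert p <= 0.05

    def test_strong_trend_significant_with_z_statistic(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(-2, 0.1, 12), rng.normal(0, 0.1, 12),
                            rng.normal(3, 0.1, 12)])
        labels = np.repeat([0, 1, 2], 12)
        assert permutation_slope_test(v, labels, seed=1, statistic="z") <= 0.05

    def test_null_p_roughly_uniform(self):
        # under exchangeability the permutation p-value is uniform
        rng = np.random.default_rng(7)
        labels = np.repeat([0, 1, 2], 15)
        ps = [permutation_slope_test(rng.standard_normal(45), labels,
                                     n_perm=99, seed=s)
              for s in range(60)]
        ks = scipy.stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match="two runs"):
            permutation_slope_test([1, 2, 3], [0, 0, 0])


class TestActivationBaselines:
    def test_psc_hand_arithmetic(self):
        w = np.concatenate([np.full(10, 100.0), np.full(10, 101.0)])[:, None]
        psc = percent_signal_change(w, np.arange(10, 20), np.arange(10))
        assert psc[0] == pytest.approx(1.0)

    def test_psc_zero_for_equal_means(self):
        w = np.full((20, 2), 50.0)
        psc = percent_signal_change(w, np.arange(10, 20), np.arange(10))
        np.testing.assert_allclose(psc, 0.0)

    def test_psc_rejects_overlap_and_zero_baseline(self):
        w = np.ones((20, 1))
        with pytest.raises(ValueError, match="disjoint"):
            percent_signal_change(w, [1, 2], [2, 3])
        with pytest.raises(ValueError, match="zero"):
            percent_signal_change(np.zeros((20, 1)), [10], [0, 1])

    def test_cnr_matches_independent_detrend(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(30)
        cond = np.full(30, 1.7)
        w = np.concatenate([base, cond])[:, None]
        got = cnr(w, np.arange(30, 60), np.arange(30))[0]
        # independent oracle: numpy polyfit detrend of the baseline
        resid = base - np.polyval(np.polyfit(np.arange(30), base, 1),
                                  np.arange(30))
        expected = (cond.mean() - base.mean()) / resid.std(ddof=1)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_cnr_zero_for_equal_means_and_monotone_in_effect(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(40)
        vals = []
        for effect in [0.0, 0.5, 1.0, 2.0]:
            w = np.concatenate([base, base.mean() + effect
                                + rng.standard_normal(40) * 0])[:, None]
            vals.append(cnr(w, np.arange(40, 80), np.arange(40))[0])
        assert vals[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(vals) > 0)

    def test_differential_feedback_sign_conventions(self):
        raw, aligned = differential_feedback(0.2, 0.2, "aL")
        assert raw == aligned == 0.0
        # aL with a contralateral (right-hemisphere) increase is a success
        raw, aligned = differential_feedback(0.1, 0.6, "aL")
        assert raw < 0 and aligned > 0
        # antisymmetry under hemisphere swap
        r1, a1 = differential_feedback(0.1, 0.6, "aR")
        r2, a2 = differential_feedback(0.6, 0.1, "aR")
        assert r1 == -r2 and a1 == -a2


class TestJarqueBera:
    def test_symmetric_mesokurtic_sample_near_zero(self):
        # Gaussian-scores sample: zero skewness, near-zero excess kurtosis
        n = 200
        v = scipy.stats.norm.ppf((np.arange(n) + 0.5) / n)
        jb, p = jarque_bera(v)
        assert jb < 1.0
        assert p > 0.5

    def test_matches_scipy_statistic(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(500)
        jb, p = jarque_bera(v)
        ref = scipy.stats.jarque_bera(v)
        assert jb == pytest.approx(ref.statistic, rel=1e-8)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_calibration_under_normality(self):
        rng = np.random.default_rng(1)
        rejections = sum(jarque_bera(rng.standard_normal(10_000))[1] <= 0.01
                         for _ in range(50))
        assert rejections <= 3

    def test_power_against_heavy_tails(self):
        rng = np.random.default_rng(2)
        v = rng.standard_t(2, size=10_000)
        assert jarque_bera(v)[1] < 0.001

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            jarque_bera(np.ones(20))
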