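"""Single-trial GLM, Wilcoxon second level and cluster-based permutation."""

import itertools

import numpy as np
import pytest
from scipy import ndimage, stats

from wmosc.core import make_metadata
from wmosc.glm import (cluster_permutation, fit_single_trial_glm,
                       rank_sum_stats, second_level_test, signed_rank_stats)
from wmosc.spectral import TFPower


def _tf(data, freqs=None, times=None, channels=("Fz",), sfreq=50.0):
    freqs = freqs if freqs is not None else np.arange(data.shape[2]) + 2.0
    times = times if times is not None else np.arange(data.shape[3]) / sfreq
    return TFPower(data, freqs, times, tuple(channels), sfreq,
                   unit="dB_vs_baseline")


def _meta(n, rng=None, ml=None, smp=None):
    rng = rng or np.random.default_rng(0)
    ml = ml if ml is not None else rng.choice([2, 4, 6], n)
    smp = smp if smp is not None else rng.integers(0, 2, n).astype(float)
    return make_metadata(ml=ml, smp=smp)


class TestFirstLevel:
    def test_noise_free_load_slope_recovered_exactly(self):
        rng = np.random.default_rng(1)
        meta = _meta(60, rng)
        ml = meta["ml"].to_numpy(float)
        data = np.tile((2.0 * ml)[:, None, None, None], (1, 1, 4, 5))
        res = fit_single_trial_glm(_tf(data), meta)
        np.testing.assert_allclose(res.beta[1], 2.0, atol=1e-10)
        np.testing.assert_allclose(res.beta[2], 0.0, atol=1e-10)
        assert res.zero_resid.all()          # perfect fit is flagged
        assert np.isinf(res.t[1]).all()

    def test_design_uses_raw_item_counts_and_binary_success(self):
        """ML enters as {2,4,6} and SMP as {0,1}: a power surface built as
        1*ML + 10*SMP must return exactly those slopes."""
        rng = np.random.default_rng(2)
        meta = _meta(80, rng)
        ml = meta["ml"].to_numpy(float)
        smp = meta["smp"].to_numpy(float)
        data = (ml + 10.0 * smp)[:, None, None, None] * np.ones((1, 1, 3, 3))
        res = fit_single_trial_glm(_tf(data), meta)
        np.testing.assert_allclose(res.beta[1], 1.0, atol=1e-10)
        np.testing.assert_allclose(res.beta[2], 10.0, atol=1e-10)

    def test_trials_with_missing_smp_are_excluded(self):
        rng = np.random.default_rng(3)
        meta = _meta(50, rng)
        meta.loc[:9, "smp"] = np.nan
        data = rng.standard_normal((50, 1, 3, 3))
        res = fit_single_trial_glm(_tf(data), meta)
        assert res.n_trials == 40

    def test_single_class_smp_flagged_undefined_not_nan_everywhere(self):
        rng = np.random.default_rng(4)
        meta = _meta(40, rng, smp=np.ones(40))
        data = rng.standard_normal((40, 1, 3, 3))
        res = fit_single_trial_glm(_tf(data), meta)
        assert "smp" in res.undefined
        assert np.isnan(res.t[2]).all()
        assert np.isfinite(res.t[1]).all()   # load slope still estimated

    def test_null_t_statistics_are_calibrated(self):
        """Monte-Carlo oracle: with power independent of the design, t(b2)
        follows the central t distribution (1,000 replicate bins)."""
        rng = np.random.default_rng(5)
        meta = _meta(60, rng)
        data = rng.standard_normal((60, 1, 1, 1000))
        res = fit_single_trial_glm(_tf(data, times=np.arange(1000) / 50.0),
                                   meta)
        t_ml = res.t[1].ravel()
        dof = 57
        assert abs(t_ml.mean()) < 0.1
        assert t_ml.var() == pytest.approx(dof / (dof - 2), rel=0.15)

    def test_scaling_power_scales_betas_but_not_t(self):
        rng = np.random.default_rng(6)
        meta = _meta(50, rng)
        data = rng.standard_normal((50, 1, 4, 4)) + 1.0
        r1 = fit_single_trial_glm(_tf(data), meta)
        r2 = fit_single_trial_glm(_tf(3.0 * data), meta)
        np.testing.assert_allclose(r2.beta, 3.0 * r1.beta, rtol=1e-10)
        np.testing.assert_allclose(r2.t, r1.t, rtol=1e-9)


class TestSecondLevel:
    def test_six_uniformly_positive_subjects_give_exact_extreme_p(self):
        vals = np.abs(np.random.default_rng(0).standard_normal((6, 3))) + 0.1
        z, p = second_level_test(vals, "within_group_vs_zero")
        np.testing.assert_allclose(p, 2 / 2 ** 6)
        assert (z > 0).all()

    def test_signed_rank_matches_scipy_exact(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((12, 40))
        _, p = signed_rank_stats(x)
        for j in range(0, 40, 7):
            ref = stats.wilcoxon(x[:, j], mode="exact").pvalue
            assert p[j] == pytest.approx(ref, abs=1e-12)

    def test_rank_sum_matches_scipy_exact(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((8, 30)), rng.standard_normal((9, 30))
        _, p = rank_sum_stats(a, b)
        for j in range(0, 30, 5):
            ref = stats.mannwhitneyu(a[:, j], b[:, j], method="exact",
                                     alternative="two-sided").pvalue
            assert p[j] == pytest.approx(ref, abs=1e-12)

    def test_null_rejection_rates_are_nominal(self):
        """Monte-Carlo calibration at alpha = 0.05 over 1,000 replicate bins
        for both the one-sample and the two-sample test."""
        rng = np.random.default_rng(3)
        _, p1 = signed_rank_stats(rng.standard_normal((12, 1000)))
        assert 0.03 <= (p1 < 0.05).mean() <= 0.07
        _, p2 = rank_sum_stats(rng.standard_normal((10, 1000)),
                               rng.standard_normal((10, 1000)))
        assert 0.03 <= (p2 < 0.05).mean() <= 0.07

    def test_between_group_p_decreases_with_shift(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((10, 1))
        ps = []
        for shift in (0.5, 1.5, 3.0):
            _, p = rank_sum_stats(a + shift, a)
            ps.append(p[0])
        assert ps[0] > ps[1] > ps[2]

    def test_all_tied_inputs_give_p_one(self):
        z, p = signed_rank_stats(np.zeros((8, 4)))
        assert (p == 1.0).all() and (z == 0.0).all()

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="5 subjects"):
            second_level_test(np.zeros((3, 4)), "within_group_vs_zero")


def _naive_cluster_p(maps, p_init):
    """Independent oracle: exhaustive sign-flip enumeration with per-bin
    scipy Wilcoxon tests and hand-rolled flood-fill clustering."""
    n = maps.shape[0]

    def stat_maps(m):
        z = np.zeros(m.shape[1:])
        p = np.ones(m.shape[1:])
        for idx in np.ndindex(m.shape[1:]):
            col = m[(slice(None),) + idx]
            res = stats.wilcoxon(col, mode="exact")
            p[idx] = res.pvalue
            w = res.statistic  # min(W+, W-); recover signed z from ranks
            ranks = stats.rankdata(np.abs(col))
            wp = ranks[col > 0].sum()
            mu = n * (n + 1) / 4
            sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24)
            z[idx] = (wp - mu) / sd
        return z, p

    def max_mass(z, p):
        best = 0.0
        for sign in (1, -1):
            mask = (p < p_init) & (np.sign(z) == sign)
            lab, k = ndimage.label(mask)
            for i in range(1, k + 1):
                best = max(best, abs(z[lab == i].sum()))
        return best

    z_obs, p_obs = stat_maps(maps)
    observed = []
    for sign in (1, -1):
        mask = (p_obs < p_init) & (np.sign(z_obs) == sign)
        lab, k = ndimage.label(mask)
        for i in range(1, k + 1):
            observed.append(abs(z_obs[lab == i].sum()))
    null = []
    for flips in itertools.product([1, -1], repeat=n):
        flipped = maps * np.array(flips)[:, None, None]
        null.append(max_mass(*stat_maps(flipped)))
    null = np.array(null)
    return observed, null


class TestClusterPermutation:
    def test_all_zero_maps_give_empty_cluster_list(self):
        res = cluster_permutation(np.zeros((8, 6, 6)), n_perm=100, seed=0)
        assert res.clusters == []

    def test_injected_cluster_is_found_and_overlaps_the_support(self):
        """The injected support (a contiguous frequency-time patch) must be
        recovered: >= 80% of its bins inside one significant cluster."""
        rng = np.random.default_rng(1)
        maps = rng.standard_normal((10, 12, 30)) * 0.5
        support = np.zeros((12, 30), bool)
        support[4:7, 10:25] = True            # ~6 Hz, 1 s patch
        maps[:, support] += 3.0
        res = cluster_permutation(maps, n_perm=500, seed=2)
        sig = res.significant()
        assert sig
        found = np.zeros((12, 30), bool)
        bins = sig[0].bins
        found[bins[:, 0], bins[:, 1]] = True
        assert (found & support).sum() >= 0.8 * support.sum()

    def test_cluster_p_never_below_permutation_floor(self):
        rng = np.random.default_rng(3)
        maps = rng.standard_normal((10, 8, 8))
        maps[:, 2:5, 2:5] += 4.0
        res = cluster_permutation(maps, n_perm=200, seed=4)
        assert all(c.p >= 1 / 201 for c in res.clusters)

    def test_stricter_final_threshold_is_nested(self):
        rng = np.random.default_rng(5)
        maps = rng.standard_normal((12, 10, 10))
        maps[:, 1:4, 1:6] += 2.0
        res = cluster_permutation(maps, n_perm=500, seed=6)
        at_01 = {id(c) for c in res.significant(0.01)}
        at_05 = {id(c) for c in res.significant(0.05)}
        assert at_01 <= at_05

    def test_matches_exhaustive_enumeration_oracle(self):
        """Dual-route check on a tiny map: sampled-permutation cluster p
        agrees with exhaustive sign-flip enumeration (n=6, 64 flips)."""
        rng = np.random.default_rng(7)
        maps = rng.standard_normal((6, 4, 4)) * 0.8
        maps[:, 1:3, 1:3] += 1.8
        observed, null = _naive_cluster_p(maps, p_init=0.05)
        res = cluster_permutation(maps, n_perm=1000, seed=8)
        assert len(res.clusters) == len(observed)
        for c in res.clusters:
            exact_p = (1 + (null >= abs(c.mass) - 1e-9).sum()) / (len(null) + 1)
            assert c.p == pytest.approx(exact_p, abs=0.05)

    def test_between_groups_mode_detects_a_shift(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((8, 10, 10))
        b = rng.standard_normal((8, 10, 10))
        a[:, 3:6, 3:8] += 2.5
        res = cluster_permutation(a, "between_groups", subject_maps_b=b,
                                  n_perm=500, seed=10)
        assert res.significant()

    def test_seed_is_required(self):
        with pytest.raises(ValueError, match="seed"):
            cluster_permutation(np.zeros((8, 4, 4)), n_perm=100)

    def test_invalid_bins_are_excluded_from_clusters(self):
        rng = np.random.default_rng(11)
        maps = rng.standard_normal((10, 6, 6))
        maps[:, :, :] += 3.0
        valid = np.zeros((6, 6), bool)
        valid[:, :3] = True
        res = cluster_permutation(maps, n_perm=200, seed=12, valid=valid)
        for c in res.clusters:
            assert (c.bins[:, 1] < 3).all()


def test_channel_adjacency_mode_bridges_neighbouring_electrodes():
    """With tf_plus_channel adjacency, suprathreshold bins at the same
    (frequency, time) on neighbouring channels merge into one cluster."""
    from wmosc.core import standard_montage

    montage = standard_montage()
    rng = np.random.default_rng(13)
    maps = 0.3 * rng.standard_normal((10, 40, 6, 6))
    ci = [montage.index(c) for c in ("CP3", "P3")]   # montage neighbours
    for c in ci:
        maps[:, c, 2:4, 2:5] += 4.0
    merged = cluster_permutation(maps, n_perm=200, seed=14,
                                 adjacency="tf_plus_channel", montage=montage)
    split = cluster_permutation(maps, n_perm=200, seed=14,
                                adjacency="tf_4conn")
    big_merged = max(len(c.bins) for c in merged.significant())
    big_split = max(len(c.bins) for c in split.significant())
    assert big_merged >= 2 * big_split * 0.9
    channels_in_big = {tuple(b)[0] for c in merged.significant()
                       if len(c.bins) == big_merged for b in c.bins}
    assert set(ci) <= channels_in_big
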