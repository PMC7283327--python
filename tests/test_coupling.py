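"""Circular-linear PAC, trial-wise Granger causality and their trial models."""

import numpy as np
import pytest
from scipy import stats

from wmosc.core import TrialEpochs, make_metadata
from wmosc.coupling import (GCTrial, PACGrid, circular_linear_corr,
                            fit_trial_coupling_model, group_coupling_stats,
                            trial_granger, trial_pac, CouplingModelResult)
from wmosc.simulate import EffectConfig, simulate_subject


def _brute_force_ccc(phase, amp):
    """Independent route: scipy.stats.pearsonr building blocks."""
    r_ca = stats.pearsonr(np.cos(phase), amp).statistic
    r_sa = stats.pearsonr(np.sin(phase), amp).statistic
    r_cs = stats.pearsonr(np.cos(phase), np.sin(phase)).statistic
    num = r_ca ** 2 + r_sa ** 2 - 2 * r_ca * r_sa * r_cs
    return np.sqrt(num / (1 - r_cs ** 2))


class TestCircularLinear:
    def test_deterministic_cosine_dependence_gives_r_one(self):
        phi = np.linspace(-np.pi, np.pi, 500, endpoint=False)
        assert circular_linear_corr(phi, 3.0 + np.cos(phi)) == \
            pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_brute_force_formula_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            phase = rng.uniform(-np.pi, np.pi, 64)
            amp = np.abs(rng.standard_normal(64)) + 0.1
            ours = circular_linear_corr(phase, amp)
            assert abs(ours - _brute_force_ccc(phase, amp)) < 1e-12

    def test_null_bias_is_small_for_independent_samples(self):
        """Independence oracle: at n=1,000 the mean coefficient over 500
        replicates stays below 0.08 (the sqrt(2/n)-scale bias)."""
        rng = np.random.default_rng(1)
        phase = rng.uniform(-np.pi, np.pi, (500, 1000))
        amp = np.abs(rng.standard_normal((500, 1000)))
        from wmosc.coupling import _circ_lin_many

        r, _ = _circ_lin_many(phase, amp)
        assert r.mean() < 0.08

    def test_constant_amplitude_is_degenerate_zero(self):
        phi = np.linspace(-np.pi, np.pi, 100)
        r, degenerate = circular_linear_corr(phi, np.full(100, 2.0),
                                             return_degenerate=True)
        assert r == 0.0 and degenerate

    def test_rotation_and_affine_amplitude_invariance(self):
        rng = np.random.default_rng(2)
        phase = rng.uniform(-np.pi, np.pi, 200)
        amp = np.abs(rng.standard_normal(200)) + 0.5
        base = circular_linear_corr(phase, amp)
        rotated = np.angle(np.exp(1j * (phase + 1.2)))
        assert circular_linear_corr(rotated, amp) == pytest.approx(base,
                                                                   abs=1e-9)
        assert circular_linear_corr(phase, 4.0 * amp + 7.0) == \
            pytest.approx(base, abs=1e-9)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            circular_linear_corr(np.zeros(10), np.zeros(9))


@pytest.fixture(scope="module")
def coupled_subject(schedule, montage):
    eff = EffectConfig(noise_uv=2.0)   # low noise, coupling dominates
    epochs, _, truth = simulate_subject(schedule, eff, "HC", seed=31,
                                        sfreq=250.0, montage=montage,
                                        return_truth=True)
    return epochs, truth


class TestPac:
    def test_full_grid_has_the_reference_bin_counts(self):
        grid = PACGrid.full()
        assert grid.shape == (86, 116)
        assert grid.phase_freqs[0] == 1.0 and grid.phase_freqs[-1] == \
            pytest.approx(35.0)
        assert grid.amp_freqs[0] == 5.0 and grid.amp_freqs[-1] == 120.0

    def test_injected_coupling_peaks_at_its_frequency_pair(self,
                                                           coupled_subject):
        epochs, _ = coupled_subject
        grid = PACGrid.reduced()
        pac = trial_pac(epochs, ("Fz", "CP3"), grid=grid)
        mean_map = pac.data.mean(axis=0)
        i, j = np.unravel_index(mean_map.argmax(), mean_map.shape)
        assert abs(grid.phase_freqs[i] - 6.0) <= 1.0
        assert abs(grid.amp_freqs[j] - 40.0) <= 5.0
        assert pac.data.min() >= 0.0 and pac.data.max() <= 1.0

    def test_reverse_pair_shows_no_theta_gamma_coupling(self,
                                                        coupled_subject):
        """Shuffle oracle: for the CP3->Fz pair at the injected (6, 40) bin
        the observed per-trial mean must sit inside the null band obtained
        by misaligning phase and amplitude trials."""
        epochs, _ = coupled_subject
        grid = PACGrid(np.array([6.0]), np.array([40.0]),
                       amp_bandwidth=14.0)
        fwd = trial_pac(epochs, ("Fz", "CP3"), grid=grid).data[:, 0, 0]
        rev = trial_pac(epochs, ("CP3", "Fz"), grid=grid).data[:, 0, 0]
        null = []
        rng = np.random.default_rng(0)
        # misalign trials: amplitude from trial k, phase from trial perm(k)
        from wmosc.spectral import narrowband_phase_amplitude
        from wmosc.coupling import _circ_lin_many

        win = epochs.time_mask(1.8, 3.8)
        ph = narrowband_phase_amplitude(epochs, "CP3", 6.0, 0.8,
                                        "phase").values[:, win]
        am = narrowband_phase_amplitude(epochs, "Fz", 40.0, 14.0,
                                        "amplitude").values[:, win]
        for _ in range(50):
            r, _d = _circ_lin_many(ph[rng.permutation(len(ph))], am)
            null.append(r.mean())
        assert rev.mean() < np.quantile(null, 0.99)
        assert fwd.mean() > rev.mean()

    def test_window_outside_epoch_rejected(self, pure_sine):
        with pytest.raises(ValueError, match="window"):
            trial_pac(pure_sine, ("Fz", "CP3"), window=(3.0, 5.0))


def _simulate_var_pair(rng, n, coupled=True):
    """y driven by x with one-sample lag; x autonomous."""
    x = np.zeros(n + 50)
    y = np.zeros(n + 50)
    ex = rng.standard_normal(n + 50)
    ey = rng.standard_normal(n + 50)
    for t in range(1, n + 50):
        x[t] = 0.5 * x[t - 1] + ex[t]
        y[t] = 0.5 * y[t - 1] + (0.4 * x[t - 1] if coupled else 0.0) + ey[t]
    return x[50:], y[50:]


def _epochs_from_pair(xs, ys, montage, sfreq=250.0):
    n_trials, n = xs.shape
    n_lo = int(round(0.5 * sfreq))
    total = n_lo + int(round(3.8 * sfreq))
    data = np.zeros((n_trials, len(montage), total))
    start = n_lo + int(round(1.8 * sfreq))
    data[:, montage.index("Fz"), start:start + n] = xs
    data[:, montage.index("CP3"), start:start + n] = ys
    data += 0.01 * np.random.default_rng(99).standard_normal(data.shape)
    times = (np.arange(total) - n_lo) / sfreq
    meta = make_metadata(ml=[2] * n_trials)
    return TrialEpochs(data, sfreq, times, montage, meta)


class TestGranger:
    def test_independent_noise_gives_near_zero_gc(self, montage):
        """For independent series, 2*dof*GC is asymptotically chi-square with
        one degree of freedom per extra lag; both directed values must stay
        inside the joint (Bonferroni) 95% small-sample bias bound."""
        from scipy import stats as sstats

        rng = np.random.default_rng(0)
        n, trials, order = 500, 100, 5
        xs = rng.standard_normal((trials, n))
        ys = rng.standard_normal((trials, n))
        epochs = _epochs_from_pair(xs, ys, montage)
        gct = trial_granger(epochs, ("Fz", "CP3"), fixed_order=order)
        dof = n - 2 * order
        bound = sstats.chi2.ppf(0.995, order) / dof
        ok = (gct.gc_fp <= bound) & (gct.gc_pf <= bound)
        assert ok.mean() >= 0.95
        assert (gct.gc_fp >= 0).all() and (gct.gc_pf >= 0).all()

    def test_direction_recovered_on_coupled_ar_trials(self, montage):
        rng = np.random.default_rng(1)
        pairs = [_simulate_var_pair(rng, 500) for _ in range(60)]
        xs = np.array([p[0] for p in pairs])
        ys = np.array([p[1] for p in pairs])
        epochs = _epochs_from_pair(xs, ys, montage)
        gct = trial_granger(epochs, ("Fz", "CP3"), max_order=5)
        assert (gct.gc_fp > gct.gc_pf).mean() >= 0.95

    def test_mean_gc_matches_the_long_run_oracle(self, montage):
        """Oracle: GC computed from one 10^6-sample realization of the true
        process; trial means must land within 15%."""
        rng = np.random.default_rng(2)
        x, y = _simulate_var_pair(rng, 1_000_000)
        from wmosc.coupling import _fit_gc_one

        gc_long, _, _ = _fit_gc_one(x - x.mean(), y - y.mean(), 2,
                                    fixed_order=2)
        pairs = [_simulate_var_pair(rng, 500) for _ in range(80)]
        xs = np.array([p[0] for p in pairs])
        ys = np.array([p[1] for p in pairs])
        epochs = _epochs_from_pair(xs, ys, montage)
        gct = trial_granger(epochs, ("Fz", "CP3"), fixed_order=2)
        assert np.nanmean(gct.gc_fp) == pytest.approx(gc_long, rel=0.15)

    def test_delta_is_antisymmetric_under_pair_swap(self, montage):
        rng = np.random.default_rng(3)
        pairs = [_simulate_var_pair(rng, 400) for _ in range(10)]
        xs = np.array([p[0] for p in pairs])
        ys = np.array([p[1] for p in pairs])
        epochs = _epochs_from_pair(xs, ys, montage)
        fwd = trial_granger(epochs, ("Fz", "CP3"), fixed_order=3)
        rev = trial_granger(epochs, ("CP3", "Fz"), fixed_order=3)
        np.testing.assert_allclose(fwd.delta, -rev.delta, atol=1e-10)

    def test_window_shorter_than_order_budget_rejected(self, pure_sine):
        with pytest.raises(ValueError, match="10 x max_order"):
            trial_granger(pure_sine, ("Fz", "CP3"), window=(1.8, 2.0),
                          max_order=20)


class TestCouplingModel:
    def test_injected_interaction_dominates(self):
        rng = np.random.default_rng(0)
        meta = make_metadata(ml=rng.choice([2, 4, 6], 200),
                             smp=rng.integers(0, 2, 200).astype(float))
        ml = meta["ml"].to_numpy(float)
        smp = meta["smp"].to_numpy(float)
        values = 0.1 * smp * ml + 0.02 * rng.standard_normal(200)
        res = fit_trial_coupling_model(values, meta)
        slopes = {r: abs(float(res.tval(r))) for r in
                  ("ml", "smp", "ml_x_smp")}
        assert max(slopes, key=slopes.get) == "ml_x_smp"

    def test_constant_outcome_gives_zero_slopes_and_flag(self):
        rng = np.random.default_rng(1)
        meta = make_metadata(ml=rng.choice([2, 4, 6], 60),
                             smp=rng.integers(0, 2, 60).astype(float))
        res = fit_trial_coupling_model(np.full(60, 0.7), meta)
        np.testing.assert_allclose(res.beta[1:], 0.0, atol=1e-10)
        assert res.zero_resid

    def test_model_has_the_four_term_design(self):
        rng = np.random.default_rng(2)
        meta = make_metadata(ml=rng.choice([2, 4, 6], 60),
                             smp=rng.integers(0, 2, 60).astype(float))
        res = fit_trial_coupling_model(rng.standard_normal(60), meta)
        assert res.regressors == ("intercept", "ml", "smp", "ml_x_smp")

    def test_single_smp_class_rejected(self):
        meta = make_metadata(ml=[2, 4, 6] * 10, smp=np.ones(30))
        with pytest.raises(ValueError, match="SMP classes"):
            fit_trial_coupling_model(np.zeros(30), meta)


def _fake_model(t_values):
    t = np.asarray(t_values, float)
    return CouplingModelResult(("intercept", "ml", "smp", "ml_x_smp"),
                               np.zeros_like(t), t, 200)


class TestGroupStats:
    def test_scalar_sign_pattern_and_bonferroni(self):
        rng = np.random.default_rng(0)
        results, groups = [], []
        for _ in range(8):   # HC-like: negative smp, positive interaction
            results.append(_fake_model([0, 0.2, -2.5, 2.5]
                                       + 0.3 * rng.standard_normal(4)))
            groups.append("HC")
        for _ in range(8):   # MS-like: null
            results.append(_fake_model(0.3 * rng.standard_normal(4)))
            groups.append("MS")
        rep = group_coupling_stats(results, groups, seed=1)
        assert rep["smp"]["HC"]["median_t"] < 0
        assert rep["smp"]["HC"]["p_bonferroni"] < 0.05
        assert rep["ml_x_smp"]["HC"]["median_t"] > 0
        assert rep["ml_x_smp"]["HC"]["p_bonferroni"] < 0.05
        assert rep["smp"]["MS"]["p"] > 0.05
        assert rep["smp"]["between"]["p_bonferroni"] < 0.05

    def test_map_mode_runs_cluster_tests(self):
        rng = np.random.default_rng(1)
        results, groups = [], []
        for g in ("HC",) * 6 + ("MS",) * 6:
            t = rng.standard_normal((4, 6, 8)) * 0.5
            if g == "HC":
                t[3, 2:4, 3:6] += 3.0     # interaction cluster
            results.append(CouplingModelResult(
                ("intercept", "ml", "smp", "ml_x_smp"),
                np.zeros_like(t), t, 100))
            groups.append(g)
        rep = group_coupling_stats(results, groups, seed=2, n_perm=300,
                                   p_cluster=0.05)
        assert rep["ml_x_smp"]["HC"]["significant"]
        assert not rep["ml_x_smp"]["MS"]["significant"]
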