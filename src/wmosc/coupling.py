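"""Trial-level directed and cross-frequency coupling between electrode pairs.

Granger causality (GC): per trial, a bivariate autoregressive model is fitted
to the two channels over an analysis window (default the 1.8-3.8 s
maintenance period), with the order chosen by BIC up to ``max_order``.
GC(x->y) = ln(sigma^2_reduced / sigma^2_full) compares the residual variance
of y predicted from its own past against prediction from both pasts; it is
nonnegative by construction. The modeled per-trial outcome is the signed
difference dGC = GC(frontal->parietal) - GC(parietal->frontal): positive
values indicate frontal-to-parietal dominance.

Phase-amplitude coupling (PAC): for every (low, high) frequency pair on a
grid, the circular-linear correlation between the low-band phase of the
first channel and the high-band amplitude envelope of the second channel is
computed over the maintenance window of each trial, giving a per-trial
coefficient map. The full grid spans 1-35 Hz phase (0.4 Hz steps, 0.8 Hz
bands) by 5-120 Hz amplitude (1 Hz steps, 5 Hz bands) — 86 x 116 pairs; a
reduced grid is provided for fast exploratory runs.

Both per-trial quantities are then modeled against the task by
value = b1 + b2*ML + b3*SMP + b4*SMP*ML per subject, and the regressor
t-values are tested at the group level with Wilcoxon statistics (Bonferroni
over the four regressors for scalar GC; cluster-based permutation over the
frequency-pair grid for PAC maps, final cluster threshold p < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TrialEpochs
from .glm import (cluster_permutation, ols_tmaps, rank_sum_stats,
                  signed_rank_stats)
from .spectral import narrowband_phase_amplitude

__all__ = [
    "PACGrid", "GCTrial", "PACTrialMap", "CouplingModelResult",
    "circular_linear_corr", "trial_pac", "trial_granger",
    "fit_trial_coupling_model", "group_coupling_stats",
]

MAINTENANCE_WINDOW = (1.8, 3.8)


# ---------------------------------------------------------------------------
# Circular-linear correlation

def circular_linear_corr(phase: np.ndarray, amplitude: np.ndarray,
                         return_degenerate: bool = False):
    """Circular-linear correlation between a phase and a linear variable.

    r = sqrt((r_ca^2 + r_sa^2 - 2 r_ca r_sa r_cs) / (1 - r_cs^2)) with
    r_ca = corr(cos(phase), a), r_sa = corr(sin(phase), a) and
    r_cs = corr(cos(phase), sin(phase)); r lies in [0, 1]. Degenerate inputs
    (zero amplitude variance, or phase concentrated so the system is
    singular) return 0, flagged when ``return_degenerate`` is set.
    """
    phase = np.asarray(phase, float)
    amplitude = np.asarray(amplitude, float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude must have equal length")
    if phase.shape[-1] < 8:
        raise ValueError("need at least 8 samples")
    r, degenerate = _circ_lin_many(phase[None, :], amplitude[None, :])
    r, degenerate = float(r[0]), bool(degenerate[0])
    return (r, degenerate) if return_degenerate else r


def _corr_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    num = (xc * yc).sum(axis=-1)
    den = np.sqrt((xc ** 2).sum(axis=-1) * (yc ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def _circ_lin_many(phase: np.ndarray, amp: np.ndarray):
    """Row-wise circular-linear correlation for (..., n) arrays."""
    c, s = np.cos(phase), np.sin(phase)
    r_ca = _corr_rows(c, amp)
    r_sa = _corr_rows(s, amp)
    r_cs = _corr_rows(c, s)
    amp_var = amp.var(axis=-1)
    denom = 1.0 - r_cs ** 2
    degenerate = (amp_var <= 0) | (denom <= 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (r_ca ** 2 + r_sa ** 2 - 2.0 * r_ca * r_sa * r_cs) / denom
    r = np.sqrt(np.clip(r2, 0.0, 1.0))
    return np.where(degenerate, 0.0, r), degenerate


# ---------------------------------------------------------------------------
# PAC grids and per-trial maps

@dataclass(frozen=True)
class PACGrid:
    """Phase/amplitude frequency grids (centers in Hz plus band widths)."""

    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    phase_bandwidth: float = 0.8
    amp_bandwidth: float = 5.0

    @classmethod
    def full(cls) -> "PACGrid":
        """The reference grid: 1-35 Hz by 0.4 Hz and 5-120 Hz by 1 Hz."""
        return cls(np.arange(1.0, 35.0 + 1e-9, 0.4),
                   np.arange(5.0, 120.0 + 1e-9, 1.0))

    @classmethod
    def reduced(cls) -> "PACGrid":
        """Fast 8 x 12 grid spanning theta-beta phase by gamma amplitude.

        The amplitude bandwidth is 14 Hz: amplitude modulation at a phase
        frequency f puts sidebands at carrier +- f, so the amplitude band
        must be wider than twice the phase frequency for the coupling to
        survive filtering. The narrow reference bandwidth of the full grid
        cannot carry theta-rate modulation for that reason.
        """
        return cls(np.arange(2.0, 10.0), np.arange(20.0, 78.0, 5.0),
                   phase_bandwidth=0.8, amp_bandwidth=14.0)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.phase_freqs), len(self.amp_freqs)


@dataclass
class PACTrialMap:
    """Per-trial circular-linear coefficient maps for an ordered channel pair."""

    data: np.ndarray            # (n_trials, n_phase, n_amp), in [0, 1]
    grid: PACGrid
    pair: tuple[str, str]       # (phase channel, amplitude channel)
    window: tuple[float, float]
    degenerate: np.ndarray = None

    def __post_init__(self) -> None:
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError("map dimensions do not match the grid")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.data.shape, bool)


def trial_pac(epochs: TrialEpochs, pair: tuple[str, str],
              window: tuple[float, float] = MAINTENANCE_WINDOW,
              grid: PACGrid | None = None) -> PACTrialMap:
    """Per-trial PAC maps: phase from ``pair[0]``, amplitude from ``pair[1]``.

    Band-pass filtering and the Hilbert transform run on the whole epoch (to
    keep filter transients away from the analysis window); the correlation is
    then computed over the half-open ``window``.
    """
    grid = grid if grid is not None else PACGrid.reduced()
    t0, t1 = window
    if t0 < epochs.times[0] or t1 > epochs.times[-1] + 1.0 / epochs.sfreq:
        raise ValueError(f"window [{t0}, {t1}) s outside the epoch")
    win = epochs.time_mask(t0, t1)
    phases = [narrowband_phase_amplitude(epochs, pair[0], f,
                                         grid.phase_bandwidth, "phase")
              .values[:, win] for f in grid.phase_freqs]
    amps = [narrowband_phase_amplitude(epochs, pair[1], f,
                                       grid.amp_bandwidth, "amplitude")
            .values[:, win] for f in grid.amp_freqs]
    n_trials = epochs.n_trials
    out = np.zeros((n_trials,) + grid.shape)
    degen = np.zeros_like(out, dtype=bool)
    for i, ph in enumerate(phases):
        for j, am in enumerate(amps):
            r, d = _circ_lin_many(ph, am)
            out[:, i, j] = r
            degen[:, i, j] = d
    return PACTrialMap(out, grid, tuple(pair), (t0, t1), degen)


# ---------------------------------------------------------------------------
# Trial-wise Granger causality

@dataclass
class GCTrial:
    """Per-trial directed GC for an ordered (frontal, parietal) pair."""

    gc_fp: np.ndarray           # frontal -> parietal
    gc_pf: np.ndarray           # parietal -> frontal
    order: np.ndarray           # chosen AR order per trial
    window: tuple[float, float]
    pair: tuple[str, str]
    failed: np.ndarray = None   # trials excluded (unstable/singular fits)

    def __post_init__(self) -> None:
        if self.failed is None:
            self.failed = np.zeros(len(self.gc_fp), bool)

    @property
    def delta(self) -> np.ndarray:
        """dGC = GC(frontal->parietal) - GC(parietal->frontal)."""
        return self.gc_fp - self.gc_pf


def _lag_matrix(x: np.ndarray, y: np.ndarray, order: int):
    """Past-value design for a bivariate AR fit on one trial."""
    n = len(x)
    rows = n - order
    cols = []
    for lag in range(1, order + 1):
        cols.append(x[order - lag:n - lag])
        cols.append(y[order - lag:n - lag])
    return np.column_stack(cols), x[order:], y[order:]


def _ar_residual_var(target: np.ndarray, design: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ beta
    return float(resid @ resid) / len(target)


def _fit_gc_one(x: np.ndarray, y: np.ndarray, max_order: int,
                fixed_order: int | None):
    """(gc_xy, gc_yx, order) for one demeaned trial window."""
    n = len(x)
    orders = [fixed_order] if fixed_order else range(1, max_order + 1)
    best = (np.inf, None)
    X_full, tx, ty = _lag_matrix(x, y, max_order if not fixed_order
                                 else fixed_order)
    rows = len(tx)
    for p in orders:
        # columns for lags 1..p (x and y interleaved)
        cols = X_full[:, :2 * p]
        bx, _, _, _ = np.linalg.lstsq(cols, tx, rcond=None)
        by, _, _, _ = np.linalg.lstsq(cols, ty, rcond=None)
        rx = tx - cols @ bx
        ry = ty - cols @ by
        cov = np.cov(np.vstack([rx, ry]))
        det = np.linalg.det(cov)
        if det <= 0:
            continue
        bic = rows * np.log(det) + 4 * p * np.log(rows)
        if bic < best[0]:
            best = (bic, p)
    if best[1] is None:
        return np.nan, np.nan, 0
    p = best[1]
    cols = X_full[:, :2 * p]
    x_cols = cols[:, 0::2]
    y_cols = cols[:, 1::2]
    var_y_full = _ar_residual_var(ty, cols)
    var_y_red = _ar_residual_var(ty, y_cols)
    var_x_full = _ar_residual_var(tx, cols)
    var_x_red = _ar_residual_var(tx, x_cols)
    if min(var_y_full, var_x_full) <= 0:
        return np.nan, np.nan, p
    gc_xy = max(0.0, np.log(var_y_red / var_y_full))
    gc_yx = max(0.0, np.log(var_x_red / var_x_full))
    return gc_xy, gc_yx, p


def trial_granger(epochs: TrialEpochs, pair: tuple[str, str] = ("Fz", "CP3"),
                  window: tuple[float, float] = MAINTENANCE_WINDOW,
                  max_order: int = 20,
                  fixed_order: int | None = None) -> GCTrial:
    """Bivariate time-domain Granger causality per trial.

    Each trial's window is demeaned and fitted with a bivariate AR model
    whose order minimises the BIC (up to ``max_order``; set ``fixed_order``
    for fully reproducible order choice). Trials whose fit degenerates are
    flagged ``failed`` and carry NaN.
    """
    win = epochs.time_mask(*window)
    n_win = int(win.sum())
    if n_win < 10 * (fixed_order or max_order):
        raise ValueError("window must span >= 10 x max_order samples")
    x = epochs.get_channel(pair[0])[:, win]
    y = epochs.get_channel(pair[1])[:, win]
    x = x - x.mean(axis=-1, keepdims=True)
    y = y - y.mean(axis=-1, keepdims=True)
    n_trials = epochs.n_trials
    gc_fp = np.full(n_trials, np.nan)
    gc_pf = np.full(n_trials, np.nan)
    order = np.zeros(n_trials, int)
    for i in range(n_trials):
        gc_fp[i], gc_pf[i], order[i] = _fit_gc_one(x[i], y[i], max_order,
                                                   fixed_order)
    failed = ~np.isfinite(gc_fp)
    return GCTrial(gc_fp, gc_pf, order, window, tuple(pair), failed)


# ---------------------------------------------------------------------------
# Trial-level regression models and group statistics

@dataclass
class CouplingModelResult:
    """Per-subject four-term model of a per-trial coupling quantity."""

    regressors: tuple[str, ...]   # ("intercept", "ml", "smp", "ml_x_smp")
    beta: np.ndarray              # (4, ...) scalar or map-shaped
    t: np.ndarray
    n_trials: int
    undefined: dict = field(default_factory=dict)
    zero_resid: np.ndarray | None = None

    def tval(self, regressor: str) -> np.ndarray:
        return self.t[self.regressors.index(regressor)]


def fit_trial_coupling_model(values: np.ndarray,
                             meta: pd.DataFrame) -> CouplingModelResult:
    """OLS of a per-trial coupling value on [1, ML, SMP, SMP*ML].

    ``values`` is (n_trials,) for scalar dGC or (n_trials, n_phase, n_amp)
    for PAC maps. Trials with missing SMP or non-finite values are dropped;
    rank-deficient designs flag the affected terms undefined.
    """
    values = np.asarray(values, float)
    finite = np.isfinite(values.reshape(len(values), -1)).all(axis=1)
    usable = meta["smp"].notna().to_numpy() & finite
    if usable.sum() < 20:
        raise ValueError("need at least 20 usable trials")
    ml = meta.loc[usable, "ml"].to_numpy(float)
    smp = meta.loc[usable, "smp"].to_numpy(float)
    if len(np.unique(smp)) < 2:
        raise ValueError("both SMP classes must be present")
    X = np.c_[np.ones(usable.sum()), ml, smp, ml * smp]
    undefined = {}
    if np.linalg.matrix_rank(X) < 4:
        undefined["design"] = "rank-deficient [1, ML, SMP, SMP*ML] design"
        X = X[:, :3]
    y = values[usable]
    if y.ndim == 1:
        y = y[:, None]
        scalar = True
    else:
        scalar = False
    beta_fit, t_fit, zero_resid = ols_tmaps(y, X)
    k = X.shape[1]
    shape = y.shape[1:]
    beta = np.zeros((4,) + shape)
    t = np.full((4,) + shape, np.nan)
    beta[:k] = beta_fit
    t[:k] = t_fit
    if scalar:
        beta, t, zero_resid = beta[:, 0], t[:, 0], zero_resid[0]
    return CouplingModelResult(("intercept", "ml", "smp", "ml_x_smp"),
                               beta, t, int(usable.sum()), undefined,
                               zero_resid)


def _bonferroni(p: float, k: int) -> float:
    return min(1.0, p * k)


def group_coupling_stats(results: list[CouplingModelResult],
                         groups: list[str], seed: int = 0,
                         n_perm: int = 1000, p_init: float = 0.05,
                         p_cluster: float = 0.01) -> dict:
    """Group-level tests of the four coupling-model regressors.

    Scalar (GC) models: per regressor, within-group signed-rank of subject
    t-values against zero and a between-group rank-sum, both Bonferroni
    corrected over the 4 regressors. Map (PAC) models: cluster-based
    permutation over the frequency-pair grid per group and regressor with
    initial threshold ``p_init`` and final cluster threshold ``p_cluster``
    (default 0.01), plus a between-group cluster test.
    """
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    t_all = np.stack([r.t for r in results])     # (subj, 4, ...)
    regs = results[0].regressors
    scalar = t_all.ndim == 2
    report: dict = {"regressors": regs, "groups": labels, "scalar": scalar}
    rng = np.random.default_rng(seed)
    for gi, reg in enumerate(regs):
        entry: dict = {}
        for lab in labels:
            sel = t_all[groups == lab, gi]
            if sel.shape[0] < 5:
                entry[lab] = {"skipped": "fewer than 5 subjects"}
                continue
            if scalar:
                z, p = signed_rank_stats(sel[:, None])
                entry[lab] = {
                    "median_t": float(np.median(sel)),
                    "z": float(z[0]), "p": float(p[0]),
                    "p_bonferroni": _bonferroni(float(p[0]), len(regs)),
                }
            else:
                res = cluster_permutation(
                    sel, "within_group_vs_zero", n_perm=n_perm,
                    p_init=p_init, p_cluster=p_cluster,
                    rng=rng)
                entry[lab] = {
                    "n_clusters": len(res.clusters),
                    "significant": [
                        {"mass": c.mass, "p": c.p, "n_bins": len(c.bins)}
                        for c in res.significant()],
                    "cluster_result": res,
                }
        if len(labels) == 2:
            a = t_all[groups == labels[0], gi]
            b = t_all[groups == labels[1], gi]
            if min(a.shape[0], b.shape[0]) >= 5:
                if scalar:
                    z, p = rank_sum_stats(a[:, None], b[:, None])
                    entry["between"] = {
                        "z": float(z[0]), "p": float(p[0]),
                        "p_bonferroni": _bonferroni(float(p[0]), len(regs)),
                    }
                else:
                    res = cluster_permutation(
                        a, "between_groups", subject_maps_b=b,
                        n_perm=n_perm, p_init=p_init, p_cluster=p_cluster,
                        rng=rng)
                    entry["between"] = {
                        "n_clusters": len(res.clusters),
                        "significant": [
                            {"mass": c.mass, "p": c.p, "n_bins": len(c.bins)}
                            for c in res.significant()],
                        "cluster_result": res,
                    }
        report[reg] = entry
    return report
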