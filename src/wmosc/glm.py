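"""Single-trial GLM on time-frequency power and nonparametric group statistics.

First level: per subject, ordinary least squares of dB power against memory
load and success, Power(f,t) = b1 + b2*ML + b3*SMP, fitted independently at
every (channel, frequency, time) bin; the regressor t-values are the
subject-level summary passed to the group stage.

Second level: Wilcoxon signed-rank (within group, subject t-values against
zero) or rank-sum (between groups) per bin, with exact null distributions for
small samples and a normal approximation (continuity- and tie-corrected)
otherwise.

Multiple comparisons over time-frequency charts are controlled by a
cluster-based permutation test: bins below the initial threshold are grouped
into same-sign clusters by adjacency, each cluster is scored by the sum of
its signed standardized statistics (cluster mass), and the observed masses
are referred to the permutation distribution of the maximal absolute mass
(sign-flipping subjects within group, or shuffling group labels between
groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import Montage
from .spectral import TFPower

__all__ = [
    "GLMResult", "ClusterResult", "Cluster",
    "ols_tmaps", "fit_single_trial_glm",
    "signed_rank_stats", "rank_sum_stats", "second_level_test",
    "cluster_permutation", "channel_adjacency",
]


# ---------------------------------------------------------------------------
# Ordinary least squares over many bins at once

def ols_tmaps(y: np.ndarray, design: np.ndarray):
    """OLS of ``y`` (n_obs, *bins) on ``design`` (n_obs, k) at every bin.

    Returns ``(beta, t, zero_resid)`` with ``beta``/``t`` shaped (k, *bins).
    Bins with (numerically) zero residual variance are flagged in
    ``zero_resid`` and get t = +-inf there rather than NaN.
    """
    X = np.asarray(design, float)
    n, k = X.shape
    shape = y.shape[1:]
    Y = y.reshape(n, -1)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - k
    ss = (resid ** 2).sum(axis=0)
    scale = np.abs(Y).max(axis=0)
    zero_resid = ss <= (1e-12 * np.maximum(scale, 1.0)) ** 2 * n
    sigma2 = ss / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
        # perfect fits: the slope is exact, the t statistic is unbounded
        t[:, zero_resid] = np.sign(beta[:, zero_resid]) * np.inf
    return (beta.reshape((k,) + shape), t.reshape((k,) + shape),
            zero_resid.reshape(shape))


@dataclass
class GLMResult:
    """Per-subject first-level maps for the [1, ML, SMP] design."""

    regressors: tuple[str, ...]            # ("intercept", "ml", "smp")
    beta: np.ndarray                       # (3, channels, freqs, times)
    t: np.ndarray                          # (3, channels, freqs, times)
    n_trials: int
    freqs: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    valid: np.ndarray                      # (freqs, times) edge-validity mask
    undefined: dict = field(default_factory=dict)
    zero_resid: np.ndarray | None = None

    def tmap(self, regressor: str) -> np.ndarray:
        return self.t[self.regressors.index(regressor)]


def fit_single_trial_glm(tfr: TFPower, meta: pd.DataFrame) -> GLMResult:
    """Fit Power(f,t) = b1 + b2*ML + b3*SMP per (channel, frequency, time).

    ML enters with its raw item counts {2, 4, 6} and SMP as the 0/1 success
    indicator; trials with missing SMP (no response) are excluded. Regressors
    that are constant in the usable trials are flagged undefined (their
    t-values are not interpretable and are excluded from clustering
    downstream) instead of propagating NaN.
    """
    if tfr.unit != "dB_vs_baseline":
        raise ValueError("GLM expects dB-baselined power")
    usable = meta["smp"].notna().to_numpy()
    if usable.sum() < 10:
        raise ValueError("need at least 10 usable trials")
    ml = meta.loc[usable, "ml"].to_numpy(float)
    smp = meta.loc[usable, "smp"].to_numpy(float)
    undefined = {}
    if len(np.unique(ml)) < 2:
        undefined["ml"] = "memory load constant across usable trials"
    if len(np.unique(smp)) < 2:
        undefined["smp"] = "only one SMP class present"
    X = np.c_[np.ones(usable.sum()), ml, smp]
    cols = [True, "ml" not in undefined, "smp" not in undefined]
    beta = np.zeros((3,) + tfr.data.shape[1:])
    t = np.full((3,) + tfr.data.shape[1:], np.nan)
    b_fit, t_fit, zero_resid = ols_tmaps(tfr.data[usable][:, ...],
                                         X[:, cols])
    beta[cols] = b_fit
    t[cols] = t_fit
    return GLMResult(("intercept", "ml", "smp"), beta, t,
                     int(usable.sum()), tfr.freqs, tfr.times,
                     tuple(tfr.channels), tfr.valid, undefined, zero_resid)


# ---------------------------------------------------------------------------
# Exact small-sample null distributions

@lru_cache(maxsize=32)
def _signed_rank_cdf(n: int) -> np.ndarray:
    """CDF of the Wilcoxon signed-rank statistic W+ under H0 (no ties)."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    pmf = counts / counts.sum()
    return np.cumsum(pmf)


@lru_cache(maxsize=32)
def _rank_sum_cdf(n1: int, n2: int) -> np.ndarray:
    """CDF of the group-1 rank sum R1 over ranks 1..n1+n2 under H0 (no ties)."""
    n = n1 + n2
    min_r = n1 * (n1 + 1) // 2
    max_r = n1 * (2 * n - n1 + 1) // 2
    # ways[k, s] = number of k-subsets of {1..r} with sum s
    ways = np.zeros((n1 + 1, max_r + 1))
    ways[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            ways[k, r:] += ways[k - 1, :-r]
    pmf = ways[n1, min_r:max_r + 1]
    pmf /= pmf.sum()
    cdf = np.zeros(max_r + 1)
    cdf[min_r:] = np.cumsum(pmf)
    return cdf


def _two_sided_from_cdf(stat: np.ndarray, cdf: np.ndarray) -> np.ndarray:
    """Two-sided exact p for an integer statistic with a symmetric null."""
    s = np.clip(np.rint(stat).astype(int), 0, len(cdf) - 1)
    lower = cdf[s]
    upper = 1.0 - np.where(s > 0, cdf[s - 1], 0.0)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


# ---------------------------------------------------------------------------
# Vectorised second-level statistics

EXACT_N_MAX = 25


def _has_ties(x: np.ndarray) -> np.ndarray:
    xs = np.sort(x, axis=0)
    return (np.diff(xs, axis=0) == 0).any(axis=0)


def signed_rank_stats(x: np.ndarray):
    """Wilcoxon signed-rank of columns of ``x`` (n, *bins) against zero.

    Returns (z, p): ``z`` is the signed standardized statistic, ``p``
    two-sided (exact for n <= 25 tie-free bins; tie-corrected normal
    approximation with continuity correction otherwise). Bins where every
    value is zero get z = 0, p = 1.
    """
    shape = x.shape[1:]
    X = x.reshape(x.shape[0], -1)
    n = X.shape[0]
    ranks = stats.rankdata(np.abs(X), axis=0)
    w = (ranks * (X > 0)).sum(axis=0)
    mu = n * (n + 1) / 4.0
    sig2 = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction on |x| ranks
    tie_corr = np.zeros(X.shape[1])
    tied = _has_ties(np.abs(X)) | (X == 0).any(axis=0)
    if tied.any():
        for j in np.flatnonzero(tied):
            _, cnt = np.unique(np.abs(X[:, j]), return_counts=True)
            tie_corr[j] = (cnt ** 3 - cnt).sum() / 48.0
    sigma = np.sqrt(np.maximum(sig2 - tie_corr, 1e-12))
    z = (w - mu) / sigma
    cc = np.clip(np.abs(w - mu) - 0.5, 0.0, None)
    p = 2.0 * stats.norm.sf(cc / sigma)
    if n <= EXACT_N_MAX:
        clean = ~tied
        if clean.any():
            p[clean] = _two_sided_from_cdf(w[clean], _signed_rank_cdf(n))
    all_zero = (X == 0).all(axis=0)
    z[all_zero] = 0.0
    p[all_zero] = 1.0
    return z.reshape(shape), np.minimum(p, 1.0).reshape(shape)


def rank_sum_stats(a: np.ndarray, b: np.ndarray):
    """Wilcoxon rank-sum (Mann-Whitney) of group a vs b per bin.

    Returns (z, p) with z > 0 when group a tends larger. Exact two-sided p
    for tie-free bins with min(n1, n2) <= 25, otherwise tie-corrected normal
    approximation with continuity correction.
    """
    n1, n2 = a.shape[0], b.shape[0]
    shape = a.shape[1:]
    A = a.reshape(n1, -1)
    B = b.reshape(n2, -1)
    X = np.concatenate([A, B], axis=0)
    ranks = stats.rankdata(X, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    tied = _has_ties(X)
    tie_corr = np.zeros(X.shape[1])
    if tied.any():
        for j in np.flatnonzero(tied):
            _, cnt = np.unique(X[:, j], return_counts=True)
            tie_corr[j] = (cnt ** 3 - cnt).sum() / (n * (n - 1))
    sig2 = n1 * n2 / 12.0 * ((n + 1) - tie_corr)
    sigma = np.sqrt(np.maximum(sig2, 1e-12))
    z = (r1 - mu) / sigma
    cc = np.clip(np.abs(r1 - mu) - 0.5, 0.0, None)
    p = 2.0 * stats.norm.sf(cc / sigma)
    if min(n1, n2) <= EXACT_N_MAX and n <= 60:
        clean = ~tied
        if clean.any():
            p[clean] = _two_sided_from_cdf(r1[clean], _rank_sum_cdf(n1, n2))
    all_tied = (X == X[0]).all(axis=0)
    z[all_tied] = 0.0
    p[all_tied] = 1.0
    return z.reshape(shape), np.minimum(p, 1.0).reshape(shape)


def second_level_test(tmaps, mode: str = "within_group_vs_zero",
                      tmaps_b=None):
    """Group-level nonparametric test per bin.

    ``within_group_vs_zero``: signed-rank of subject maps against zero.
    ``between_groups``: rank-sum of group ``tmaps`` vs ``tmaps_b``.
    Returns (z, p) arrays with the shape of one subject map.
    """
    maps = np.asarray(tmaps, float)
    if mode == "within_group_vs_zero":
        if maps.shape[0] < 5:
            raise ValueError("need >= 5 subjects")
        return signed_rank_stats(maps)
    if mode == "between_groups":
        other = np.asarray(tmaps_b, float)
        if maps.shape[0] < 5 or other.shape[0] < 5:
            raise ValueError("need >= 5 subjects per group")
        return rank_sum_stats(maps, other)
    raise ValueError(f"unknown mode '{mode}'")


# ---------------------------------------------------------------------------
# Cluster-based permutation

@dataclass
class Cluster:
    bins: np.ndarray        # (n_bins, ndim) integer indices into the map
    mass: float             # sum of signed standardized statistics
    p: float                # permutation p-value


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_perm: int
    p_init: float
    p_cluster: float
    z: np.ndarray
    p_map: np.ndarray
    null_max_mass: np.ndarray | None = None

    def significant(self, threshold: float | None = None) -> list[Cluster]:
        thr = self.p_cluster if threshold is None else threshold
        return [c for c in self.clusters if c.p < thr]


def channel_adjacency(montage: Montage, factor: float = 1.5) -> np.ndarray:
    """Boolean neighbour matrix: channels within ``factor`` x the median
    nearest-neighbour chordal distance."""
    pos = montage.positions
    d = np.sqrt(((pos[:, None] - pos[None]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    thr = factor * np.median(d.min(axis=1))
    adj = d <= thr
    return adj | adj.T


def _label_clusters(mask: np.ndarray, z: np.ndarray, adjacency: str,
                    chan_adj: np.ndarray | None):
    """Label same-sign suprathreshold clusters; returns (labels, n).

    2-D maps use 4-connectivity over (frequency, time). 3-D maps
    (channel, frequency, time) are labelled per channel; with
    ``tf_plus_channel`` labels are merged across neighbouring channels that
    are suprathreshold at the same (frequency, time) bin.
    """
    structure = ndimage.generate_binary_structure(2, 1)
    if mask.ndim == 2:
        return ndimage.label(mask, structure=structure)
    labels = np.zeros(mask.shape, dtype=np.int32)
    offset = 0
    for c in range(mask.shape[0]):
        lab, k = ndimage.label(mask[c], structure=structure)
        labels[c] = np.where(lab > 0, lab + offset, 0)
        offset += k
    if adjacency == "tf_plus_channel" and chan_adj is not None:
        parent = np.arange(offset + 1)

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        pairs = np.argwhere(np.triu(chan_adj, 1))
        for i, j in pairs:
            both = mask[i] & mask[j]
            if both.any():
                for li, lj in zip(labels[i][both], labels[j][both]):
                    ri, rj = find(li), find(lj)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
        if offset:
            root = np.array([find(i) for i in range(offset + 1)])
            uniq = np.unique(root[1:])
            remap = np.zeros(offset + 1, dtype=np.int32)
            remap[uniq] = np.arange(1, len(uniq) + 1)
            labels = remap[root[labels]]
            offset = len(uniq)
    return labels, offset


def _cluster_masses(z: np.ndarray, p: np.ndarray, p_init: float,
                    valid: np.ndarray | None, adjacency: str,
                    chan_adj: np.ndarray | None, collect_bins: bool):
    supra = p < p_init
    if valid is not None:
        supra &= valid
    supra &= np.isfinite(z)
    masses, bins = [], []
    for sign in (1, -1):
        mask = supra & ((z > 0) if sign > 0 else (z < 0))
        if not mask.any():
            continue
        labels, k = _label_clusters(mask, z, adjacency, chan_adj)
        if k == 0:
            continue
        sums = ndimage.sum_labels(z, labels, index=np.arange(1, k + 1))
        masses.extend(sums.tolist())
        if collect_bins:
            bins.extend(np.argwhere(labels == idx)
                        for idx in range(1, k + 1))
    return masses, bins


def cluster_permutation(subject_maps, mode: str = "within_group_vs_zero",
                        subject_maps_b=None, n_perm: int = 1000,
                        p_init: float = 0.05, p_cluster: float = 0.05,
                        adjacency: str = "tf_4conn",
                        valid: np.ndarray | None = None,
                        montage: Montage | None = None,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None) -> ClusterResult:
    """Cluster-based permutation test on subject-level maps.

    The per-bin statistic is the second-level Wilcoxon z; the permutation
    null of the maximal absolute cluster mass is built by sign-flipping
    subjects (within-group mode) or shuffling group labels (between-groups).
    Cluster p = (1 + #{perm >= observed}) / (n_perm + 1), so p can never fall
    below 1/(n_perm + 1). An empty cluster list (no suprathreshold bins) is a
    valid result, not an error.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    if rng is None:
        if seed is None:
            raise ValueError("a permutation seed is required")
        rng = np.random.default_rng(seed)
    maps = np.asarray(subject_maps, float)
    shape = maps.shape[1:]
    chan_adj = None
    if adjacency == "tf_plus_channel":
        if montage is None:
            raise ValueError("tf_plus_channel adjacency needs the montage")
        chan_adj = channel_adjacency(montage)
    elif adjacency != "tf_4conn":
        raise ValueError(f"unknown adjacency '{adjacency}'")

    if mode == "within_group_vs_zero":
        z_obs, p_obs = signed_rank_stats(maps)
        null_max = _null_max_within(maps, n_perm, p_init, valid, adjacency,
                                    chan_adj, rng)
    elif mode == "between_groups":
        other = np.asarray(subject_maps_b, float)
        z_obs, p_obs = rank_sum_stats(maps, other)
        null_max = _null_max_between(maps, other, n_perm, p_init, valid,
                                     adjacency, chan_adj, rng)
    else:
        raise ValueError(f"unknown mode '{mode}'")

    masses, bins = _cluster_masses(z_obs, p_obs, p_init, valid, adjacency,
                                   chan_adj, collect_bins=True)
    clusters = []
    for mass, b in zip(masses, bins):
        p_val = (1.0 + np.sum(null_max >= abs(mass))) / (n_perm + 1.0)
        clusters.append(Cluster(b, float(mass), float(p_val)))
    clusters.sort(key=lambda c: c.p)
    return ClusterResult(clusters, n_perm, p_init, p_cluster, z_obs, p_obs,
                         null_max)


def _perm_max_mass(z: np.ndarray, p: np.ndarray, p_init: float,
                   valid: np.ndarray | None, adjacency: str,
                   chan_adj: np.ndarray | None) -> float:
    masses, _ = _cluster_masses(z, p, p_init, valid, adjacency, chan_adj,
                                collect_bins=False)
    return max((abs(m) for m in masses), default=0.0)


def _null_max_within(maps: np.ndarray, n_perm: int, p_init: float,
                     valid, adjacency, chan_adj,
                     rng: np.random.Generator) -> np.ndarray:
    """Sign-flip permutation null of the max |cluster mass| (vectorised W+)."""
    n = maps.shape[0]
    shape = maps.shape[1:]
    X = maps.reshape(n, -1)
    ranks = stats.rankdata(np.abs(X), axis=0)
    pos = X > 0
    w_base = (ranks * pos).sum(axis=0)
    delta = ranks * (1.0 - 2.0 * pos)          # effect of flipping subject i
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    flips = rng.integers(0, 2, size=(n_perm, n)).astype(float)
    w_perm = w_base[None, :] + flips @ delta
    z_perm = (w_perm - mu) / sigma
    exact = n <= EXACT_N_MAX
    cdf = _signed_rank_cdf(n) if exact else None
    out = np.empty(n_perm)
    for i in range(n_perm):
        w = w_perm[i]
        if exact:
            p = _two_sided_from_cdf(w, cdf)
        else:
            cc = np.clip(np.abs(w - mu) - 0.5, 0.0, None)
            p = 2.0 * stats.norm.sf(cc / sigma)
        out[i] = _perm_max_mass(z_perm[i].reshape(shape), p.reshape(shape),
                                p_init, valid, adjacency, chan_adj)
    return out


def _null_max_between(a: np.ndarray, b: np.ndarray, n_perm: int,
                      p_init: float, valid, adjacency, chan_adj,
                      rng: np.random.Generator) -> np.ndarray:
    """Label-shuffling permutation null of the max |cluster mass|."""
    n1, n2 = a.shape[0], b.shape[0]
    n = n1 + n2
    shape = a.shape[1:]
    X = np.concatenate([a, b], axis=0).reshape(n, -1)
    ranks = stats.rankdata(X, axis=0)
    mu = n1 * (n + 1) / 2.0
    sigma = np.sqrt(n1 * n2 * (n + 1) / 12.0)
    sel = np.zeros((n_perm, n))
    for i in range(n_perm):
        sel[i, rng.permutation(n)[:n1]] = 1.0
    r1 = sel @ ranks
    z_perm = (r1 - mu) / sigma
    exact = min(n1, n2) <= EXACT_N_MAX and n <= 60
    cdf = _rank_sum_cdf(n1, n2) if exact else None
    out = np.empty(n_perm)
    for i in range(n_perm):
        r = r1[i]
        if exact:
            p = _two_sided_from_cdf(r, cdf)
        else:
            cc = np.clip(np.abs(r - mu) - 0.5, 0.0, None)
            p = 2.0 * stats.norm.sf(cc / sigma)
        out[i] = _perm_max_mass(z_perm[i].reshape(shape), p.reshape(shape),
                                p_init, valid, adjacency, chan_adj)
    return out
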