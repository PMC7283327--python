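"""Band-pass filtering, threshold artifact rejection and the surface Laplacian.

The current-source-density (CSD) transform follows the spherical-spline
construction: scalp potential at each time sample is interpolated by a spline
on the unit sphere built from a Legendre series

    g(x) = (1/4pi) * sum_{n=1..N} (2n+1) / (n (n+1))^m * P_n(x)

and the surface Laplacian of that spline is obtained from the companion
series h with exponent m-1 (each degree picks up the spherical-harmonic
eigenvalue n(n+1)). The spline weights c solve (G + lambda I) c = V under a
zero-sum constraint; CSD_i = sum_j c_j h(cos theta_ij) / r^2, in uV/cm^2 for
a head radius in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import signal as sps

from .core import Montage, TrialEpochs

__all__ = ["CsdParams", "bandpass_filter", "detect_artifacts",
           "csd_matrices", "csd_operator", "csd_transform",
           "drop_artifact_trials"]


@dataclass(frozen=True)
class CsdParams:
    """Spherical-spline parameters: flexibility m, ridge lambda, series length."""

    m: int = 4
    lam: float = 1e-5
    n_terms: int = 50
    head_radius: float | None = None   # cm; None -> montage's head radius

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("spline flexibility m must be >= 2")
        if self.lam < 0:
            raise ValueError("regularization lambda must be >= 0")
        if self.n_terms < 20:
            raise ValueError("need >= 20 Legendre terms")


def bandpass_filter(epochs: TrialEpochs, low: float, high: float,
                    order: int = 4) -> TrialEpochs:
    """Zero-phase Butterworth band-pass (forward-backward, order doubled)."""
    nyq = epochs.sfreq / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [low, high], btype="bandpass",
                     fs=epochs.sfreq, output="sos")
    # even-reflection padding over the whole epoch keeps the slow high-pass
    # transient small on epoch-length data
    data = sps.sosfiltfilt(sos, epochs.data, axis=-1, padtype="even",
                           padlen=epochs.data.shape[-1] - 1)
    return dc_replace(epochs, data=data)


def detect_artifacts(epochs: TrialEpochs, threshold: float = 100.0) -> np.ndarray:
    """Per-trial boolean mask: True where any sample exceeds +-threshold uV."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.any(np.abs(epochs.data) > threshold, axis=(1, 2))


def drop_artifact_trials(epochs: TrialEpochs,
                         threshold: float = 100.0) -> tuple[TrialEpochs, int]:
    """Remove threshold-exceeding trials; returns (clean epochs, n dropped)."""
    bad = detect_artifacts(epochs, threshold)
    return epochs.select_trials(~bad), int(bad.sum())


def _legendre_series(x: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """sum_n coeffs[n-1] * P_n(x) via the three-term recurrence (n = 1..N)."""
    p_prev = np.ones_like(x)    # P_0
    p = x.copy()                # P_1
    out = coeffs[0] * p
    for n in range(1, len(coeffs)):
        p, p_prev = ((2 * n + 1) * x * p - n * p_prev) / (n + 1), p
        out += coeffs[n] * p
    return out


def csd_matrices(montage: Montage,
                 params: CsdParams) -> tuple[np.ndarray, np.ndarray]:
    """G (interpolation) and H (Laplacian) spline matrices for a montage."""
    n = np.arange(1, params.n_terms + 1, dtype=float)
    base = (2 * n + 1) / (4.0 * np.pi)
    cosang = montage.cosine_distances
    g = _legendre_series(cosang, base / (n * (n + 1)) ** params.m)
    h = _legendre_series(cosang, base / (n * (n + 1)) ** (params.m - 1))
    return g, h


def csd_operator(montage: Montage, params: CsdParams | None = None) -> np.ndarray:
    """Linear CSD operator: CSD = operator @ V for a channels-vector V.

    Solves the zero-sum-constrained spline system once; the operator applies
    to any array of potentials on this montage.
    """
    params = params if params is not None else CsdParams()
    if len(montage) < 8:
        raise ValueError("CSD needs at least 8 channels")
    g, h = csd_matrices(montage, params)
    nch = len(montage)
    A = np.zeros((nch + 1, nch + 1))
    A[:nch, :nch] = g + params.lam * np.eye(nch)
    A[:nch, nch] = 1.0
    A[nch, :nch] = 1.0
    try:
        solver = np.linalg.inv(A)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular spline system; raise the regularization lambda") from err
    radius = params.head_radius if params.head_radius is not None \
        else montage.head_radius
    # spline weights c for any V: rows of solver map [V; 0] -> [c; c0]
    take_c = solver[:nch, :nch]
    return (h @ take_c) / radius ** 2


def csd_transform(epochs: TrialEpochs,
                  params: CsdParams | None = None) -> TrialEpochs:
    """Spherical-spline surface Laplacian; output unit tag ``csd_uV_per_cm2``.

    Linear in the potential and insensitive to adding a spatially constant
    offset; the output has zero spatial mean by construction.
    """
    operator = csd_operator(epochs.montage, params)
    nch = len(epochs.montage)
    nt, _, ns = epochs.data.shape
    flat = epochs.data.transpose(1, 0, 2).reshape(nch, nt * ns)
    out = (operator @ flat).reshape(nch, nt, ns).transpose(1, 0, 2)
    return dc_replace(epochs, data=out, unit="csd_uV_per_cm2")
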