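"""Shared domain containers for epoched working-memory EEG.

The central object is :class:`TrialEpochs`: a ``trials x channels x samples``
array of scalp potential (microvolt) or current source density
(microvolt/cm^2), together with its sampling rate, epoch time axis relative to
memory-set onset, electrode montage and a per-trial metadata table.

Trial metadata is a plain :class:`pandas.DataFrame` with one row per epoch and
the columns listed in :data:`METADATA_COLUMNS`:

``ml``
    memory load, the number of consonants held in memory (2, 4 or 6).
``smp``
    successful memory performance, 1 for a correct present/absent judgement,
    0 for an error, NaN when no response was given.
``match``
    whether the probe belonged to the memory set (``"match"``/``"nonmatch"``).
``rt``
    reaction time in seconds (NaN when missing; never coded as 0).
``hand``
    response hand (``"left"``/``"right"``).
``block``, ``sub_block``
    position of the trial in the session structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "TrialEpochs",
    "BaselineSegments",
    "ClinicalScores",
    "METADATA_COLUMNS",
    "CLINICAL_TESTS",
    "STANDARD_40",
    "LEFT_TEMPOROPARIETAL",
    "MEDIAL_FRONTAL",
    "OCCIPITAL",
    "standard_montage",
    "fibonacci_montage",
    "make_metadata",
    "validate_metadata",
    "validate_epochs",
]

#: 40-channel extended 10-20 layout (frontal Fz and left parietal CP3 included).
STANDARD_40 = [
    "Fp1", "Fp2", "AFz", "F7", "F5", "F3", "Fz", "F4", "F6", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C5", "C3", "Cz", "C4", "C6", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P5", "P3", "Pz", "P4", "P6", "P8",
    "PO3", "POz", "PO4", "O1", "Oz", "O2",
]

LEFT_TEMPOROPARIETAL = ["T7", "TP7", "CP3", "P7", "P5", "P3"]
MEDIAL_FRONTAL = ["AFz", "Fz", "FCz"]
OCCIPITAL = ["PO3", "POz", "PO4", "O1", "Oz", "O2"]

METADATA_COLUMNS = ["block", "sub_block", "ml", "match", "smp", "rt", "hand"]

CLINICAL_TESTS = ["pasat", "sdmt", "bvmt", "avlt", "stroop"]

#: Required analysis epoch span (s relative to memory-set onset).
EPOCH_SPAN = (-0.5, 3.8)

#: Required baseline duration per block (s).
BASELINE_DURATION = 15.0


@dataclass(frozen=True)
class Montage:
    """Electrode names and unit-sphere 3-D positions.

    Positions are dimensionless direction vectors of norm 1; ``head_radius``
    (cm) converts angular quantities to physical units (CSD in uV/cm^2).
    """

    names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm
    head_radius: float = 10.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "names", tuple(self.names))
        if pos.shape != (len(self.names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("montage positions must lie on the unit sphere")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def pick(self, names: list[str]) -> "Montage":
        idx = [self.index(n) for n in names]
        return Montage(tuple(names), self.positions[idx], self.head_radius)

    @property
    def cosine_distances(self) -> np.ndarray:
        """cos of angular separation between every channel pair."""
        return np.clip(self.positions @ self.positions.T, -1.0, 1.0)


def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit; returns (center, radius)."""
    A = np.c_[2.0 * points, np.ones(len(points))]
    b = (points ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def standard_montage(names: list[str] | None = None, head_radius: float = 10.0) -> Montage:
    """Build the default 40-channel montage from the standard 10-05 layout.

    Positions come from the mne ``standard_1005`` template, re-centred on a
    best-fit sphere and projected to unit norm.
    """
    import warnings

    import mne

    names = list(names) if names is not None else list(STANDARD_40)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        template = mne.channels.make_standard_montage("standard_1005")
    ch_pos = template.get_positions()["ch_pos"]
    missing = [n for n in names if n not in ch_pos]
    if missing:
        raise ValueError(f"channels not in standard layout: {missing}")
    pts = np.array([ch_pos[n] for n in names], dtype=float)
    center, _ = _fit_sphere(pts)
    pts = pts - center
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return Montage(tuple(names), pts, head_radius)


def fibonacci_montage(n_channels: int = 64, head_radius: float = 10.0,
                      cap_fraction: float = 0.65) -> Montage:
    """Dense synthetic test montage: Fibonacci lattice on the upper spherical cap.

    Used for validating spatial operators (e.g. the surface Laplacian) against
    analytic spherical-harmonic results; not a physical electrode layout.
    """
    i = np.arange(n_channels)
    # z from 1 down into the cap, golden-angle azimuths
    z = 1.0 - cap_fraction * (i + 0.5) / n_channels * 2.0
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    pts = np.c_[r * np.cos(phi), r * np.sin(phi), z]
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    names = tuple(f"S{k:03d}" for k in i)
    return Montage(names, pts, head_radius)


def make_metadata(**columns) -> pd.DataFrame:
    """Assemble a trial metadata table, filling optional columns with defaults."""
    df = pd.DataFrame(columns)
    n = len(df)
    defaults = {
        "block": 1, "sub_block": 1, "ml": 2, "match": "match",
        "smp": 1.0, "rt": np.nan, "hand": "right",
    }
    for col in METADATA_COLUMNS:
        if col not in df:
            df[col] = [defaults[col]] * n
    return df[METADATA_COLUMNS].copy()


def validate_metadata(meta: pd.DataFrame) -> list[str]:
    """Return a list of invariant violations (empty when the table is valid)."""
    issues: list[str] = []
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            issues.append(f"metadata: missing column '{col}'")
    if issues:
        return issues
    ml = meta["ml"]
    if not ml.isin([2, 4, 6]).all():
        bad = sorted(set(ml[~ml.isin([2, 4, 6])]))
        issues.append(f"metadata: ml outside {{2,4,6}}: {bad}")
    smp = meta["smp"].dropna()
    if not smp.isin([0, 1]).all():
        issues.append("metadata: smp must be 0, 1 or missing")
    if not meta["match"].isin(["match", "nonmatch"]).all():
        issues.append("metadata: match flag must be 'match' or 'nonmatch'")
    if not meta["hand"].isin(["left", "right"]).all():
        issues.append("metadata: hand must be 'left' or 'right'")
    rt = meta["rt"].dropna()
    if (rt < 0).any():
        issues.append("metadata: negative reaction times")
    return issues


@dataclass
class TrialEpochs:
    """Epoched multichannel EEG with montage and per-trial metadata.

    ``data`` is trials x channels x samples; ``times`` holds seconds relative
    to memory-set onset; ``unit`` is ``"volts_uV"`` for scalp potential or
    ``"csd_uV_per_cm2"`` after the surface-Laplacian transform.
    """

    data: np.ndarray
    sfreq: float
    times: np.ndarray
    montage: Montage
    meta: pd.DataFrame
    unit: str = "volts_uV"
    info: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        return self.montage.index(name)

    def get_channel(self, name: str) -> np.ndarray:
        """(n_trials, n_samples) view of one channel."""
        return self.data[:, self.channel_index(name), :]

    def time_mask(self, t0: float, t1: float) -> np.ndarray:
        """Boolean sample mask for the half-open window [t0, t1)."""
        return (self.times >= t0) & (self.times < t1)

    def crop(self, t0: float, t1: float) -> "TrialEpochs":
        m = self.time_mask(t0, t1)
        return replace(self, data=self.data[:, :, m], times=self.times[m])

    def select_trials(self, mask: np.ndarray) -> "TrialEpochs":
        return replace(self, data=self.data[mask],
                       meta=self.meta.loc[np.asarray(mask)].reset_index(drop=True))

    def copy(self) -> "TrialEpochs":
        return replace(self, data=self.data.copy(), meta=self.meta.copy())


@dataclass
class BaselineSegments:
    """Continuous resting segments (one per block) used for dB baselining."""

    segments: list[np.ndarray]  # each (n_channels, n_samples), uV
    sfreq: float

    @property
    def n_blocks(self) -> int:
        return len(self.segments)

    def durations(self) -> list[float]:
        return [s.shape[1] / self.sfreq for s in self.segments]


@dataclass
class ClinicalScores:
    """Per-subject neuropsychological z-scores (PASAT, SDMT, BVMT-R, AVLT, Stroop)."""

    table: pd.DataFrame  # index: subject id; columns: CLINICAL_TESTS (+ 'group')

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_TESTS if c not in self.table.columns]
        if missing:
            raise ValueError(f"clinical table missing tests: {missing}")

    def scores(self, test: str) -> pd.Series:
        return self.table[test]


def validate_epochs(epochs: TrialEpochs) -> list[str]:
    """Check every container invariant; return the list of violations.

    Pure reporting: the input is never modified. An empty list means the
    epochs satisfy all invariants (valid units, epoch window covering
    [-0.5, 3.8] s, metadata aligned 1:1 with trials, montage consistency,
    legal metadata domains).
    """
    issues: list[str] = []
    d = epochs.data
    if d.ndim != 3:
        issues.append(f"data: expected 3 dims (trials, channels, samples), got {d.ndim}")
        return issues
    if d.shape[1] != len(epochs.montage):
        issues.append(
            f"data/montage: {d.shape[1]} channels in data vs {len(epochs.montage)} in montage")
    if d.shape[2] != len(epochs.times):
        issues.append("data/times: sample count mismatch")
    if d.shape[0] != len(epochs.meta):
        issues.append(
            f"data/metadata: {d.shape[0]} epochs vs {len(epochs.meta)} metadata rows")
    if epochs.unit not in ("volts_uV", "csd_uV_per_cm2"):
        issues.append(f"unit: unknown tag '{epochs.unit}'")
    if len(epochs.times) >= 2:
        dt = np.diff(epochs.times)
        if not np.allclose(dt, 1.0 / epochs.sfreq, rtol=1e-6):
            issues.append("times: axis inconsistent with sampling rate")
        t0, t1 = epochs.times[0], epochs.times[-1]
        tol = 1.0 / epochs.sfreq
        if t0 > EPOCH_SPAN[0] + tol or t1 < EPOCH_SPAN[1] - tol:
            issues.append(
                f"times: window [{t0:.3f}, {t1:.3f}] s does not span "
                f"[{EPOCH_SPAN[0]}, {EPOCH_SPAN[1]}] s")
    if not np.isfinite(d).all():
        issues.append("data: non-finite samples")
    issues.extend(validate_metadata(epochs.meta))
    return issues


def validate_baseline(baseline: BaselineSegments) -> list[str]:
    issues = []
    for k, dur in enumerate(baseline.durations()):
        if abs(dur - BASELINE_DURATION) > 0.01:
            issues.append(f"baseline block {k}: duration {dur:.3f} s != 15 s")
    return issues
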