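"""Readers and writers for epoched EEG, trial metadata and clinical scores.

Raw epochs travel either in standard raw formats (EDF, BrainVision — read via
mne, with epoch boundaries taken from annotations) or in the package's own
HDF5 container. Trial metadata always travels as a sidecar TSV keyed by
0-based trial index, so the EEG file stays a plain standard-format signal
file. Clinical scores are TSV with one row per subject.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    BaselineSegments,
    ClinicalScores,
    METADATA_COLUMNS,
    Montage,
    TrialEpochs,
    validate_epochs,
)

__all__ = [
    "ParseError", "AlignmentError",
    "metadata_sidecar_path", "write_metadata", "read_metadata",
    "write_epochs", "read_epochs", "write_epochs_edf",
    "write_clinical_scores", "read_clinical_scores",
]


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


class AlignmentError(ValueError):
    """Raised when metadata rows do not align 1:1 with epochs."""


def metadata_sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "_meta.tsv")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.insert(0, "trial", np.arange(len(out)))
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", na_values=["n/a"])
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"metadata table missing columns: {missing}")
    if "trial" in meta.columns:
        meta = meta.sort_values("trial").drop(columns=["trial"])
    return meta.reset_index(drop=True)


# ---------------------------------------------------------------------------
# HDF5 container

def write_epochs(epochs: TrialEpochs, path: str | Path,
                 baseline: BaselineSegments | None = None) -> None:
    """Write epochs (and optionally baselines) to the HDF5 container.

    Metadata goes to the ``*_meta.tsv`` sidecar next to the container.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip", compression_opts=1)
        f.create_dataset("times", data=epochs.times)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["unit"] = epochs.unit
        g = f.create_group("montage")
        g.create_dataset("names", data=np.array(epochs.montage.names, dtype="S"))
        g.create_dataset("positions", data=epochs.montage.positions)
        g.attrs["head_radius"] = epochs.montage.head_radius
        if baseline is not None:
            b = f.create_group("baseline")
            b.attrs["sfreq"] = baseline.sfreq
            for k, seg in enumerate(baseline.segments):
                b.create_dataset(f"block{k}", data=seg,
                                 compression="gzip", compression_opts=1)
    write_metadata(epochs.meta, metadata_sidecar_path(path))


def _read_container(path: Path) -> tuple[TrialEpochs, BaselineSegments | None]:
    try:
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            times = f["times"][()]
            sfreq = float(f.attrs["sfreq"])
            unit = str(f.attrs["unit"])
            names = [n.decode() for n in f["montage/names"][()]]
            montage = Montage(tuple(names), f["montage/positions"][()],
                              float(f["montage"].attrs["head_radius"]))
            baseline = None
            if "baseline" in f:
                segs = [f[f"baseline/{k}"][()] for k in sorted(f["baseline"])]
                baseline = BaselineSegments(segs, float(f["baseline"].attrs["sfreq"]))
    except (OSError, KeyError) as err:
        raise ParseError(f"not a valid epochs container: {path}: {err}") from err
    meta = read_metadata(metadata_sidecar_path(path))
    if len(meta) != data.shape[0]:
        raise AlignmentError(
            f"{len(meta)} metadata rows vs {data.shape[0]} epochs in {path.name}")
    epochs = TrialEpochs(data, sfreq, times, montage, meta, unit=unit)
    return epochs, baseline


# ---------------------------------------------------------------------------
# EDF support

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_epochs_edf(epochs: TrialEpochs, path: str | Path) -> None:
    """Write epochs to EDF+ as a continuous record with one annotation per trial.

    Epochs are concatenated back-to-back; a ``trial`` annotation marks each
    memory-set onset. Amplitude resolution is 0.1 uV (16-bit, +-3276.7 uV
    physical range); samples clip at the physical range.
    """
    if abs(epochs.sfreq - round(epochs.sfreq)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    sfreq = int(round(epochs.sfreq))
    n_trials, n_ch, n_samp = epochs.data.shape
    total = n_trials * n_samp
    n_records = int(np.ceil(total / sfreq))
    onset_in_epoch = -float(epochs.times[0])

    flat = epochs.data.transpose(1, 0, 2).reshape(n_ch, total)
    flat = np.clip(flat, -3276.7, 3276.7)
    dig = np.zeros((n_ch, n_records * sfreq), dtype="<i2")
    dig[:, :total] = np.round(flat * 10.0).astype("<i2")

    ann_len = 60  # bytes per record for the annotation signal
    ann = np.zeros((n_records, ann_len), dtype=np.uint8)
    for rec in range(n_records):
        tal = f"+{rec:d}\x14\x14\x00".encode("ascii")
        ann[rec, :len(tal)] = np.frombuffer(tal, dtype=np.uint8)
    for i in range(n_trials):
        onset = i * n_samp / sfreq + onset_in_epoch
        rec = int(onset)
        tal = f"+{onset:.4f}\x14trial\x14\x00".encode("ascii")
        row = ann[rec]
        start = int(np.max(np.nonzero(row)[0])) + 2 if row.any() else 0
        if start + len(tal) > ann_len:
            raise ValueError("annotation record overflow")
        row[start:start + len(tal)] = np.frombuffer(tal, dtype=np.uint8)

    ns = n_ch + 1
    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate 01-JAN-2000 X X X", 80),
        _edf_field(now.strftime("%d.%m.%y"), 8),
        _edf_field(now.strftime("%H.%M.%S"), 8),
        _edf_field(256 * (ns + 1), 8),
        _edf_field("EDF+C", 44),
        _edf_field(n_records, 8),
        _edf_field("1", 8),
        _edf_field(ns, 4),
    ])
    labels = [f"EEG {name}" for name in epochs.montage.names] + ["EDF Annotations"]
    sig = b"".join([
        b"".join(_edf_field(lb, 16) for lb in labels),
        b"".join(_edf_field("", 80) for _ in labels),
        b"".join(_edf_field("uV", 8) for _ in epochs.montage.names) + _edf_field("", 8),
        b"".join(_edf_field("-3276.7", 8) for _ in epochs.montage.names) + _edf_field(-1, 8),
        b"".join(_edf_field("3276.7", 8) for _ in epochs.montage.names) + _edf_field(1, 8),
        b"".join(_edf_field(-32767, 8) for _ in epochs.montage.names) + _edf_field(-32768, 8),
        b"".join(_edf_field(32767, 8) for _ in epochs.montage.names) + _edf_field(32767, 8),
        b"".join(_edf_field("", 80) for _ in labels),
        b"".join(_edf_field(sfreq, 8) for _ in epochs.montage.names)
        + _edf_field(ann_len // 2, 8),
        b"".join(_edf_field("", 32) for _ in labels),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for rec in range(n_records):
            fh.write(dig[:, rec * sfreq:(rec + 1) * sfreq].tobytes())
            fh.write(ann[rec].tobytes())


def _read_raw_epochs(path: Path, fmt: str, tmin: float, tmax: float,
                     head_radius: float) -> TrialEpochs:
    import mne

    try:
        if fmt == "edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    except Exception as err:  # noqa: BLE001 - normalise reader failures
        raise ParseError(f"could not read {fmt} file {path}: {err}") from err

    onsets = [a["onset"] for a in raw.annotations
              if a["description"].strip().lower().endswith("trial")]
    if not onsets:
        raise ParseError(f"no trial annotations found in {path}")
    sfreq = raw.info["sfreq"]
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    from .core import standard_montage
    montage = standard_montage(names, head_radius=head_radius)

    n_lo = int(round(tmin * sfreq))
    n_hi = int(round(tmax * sfreq))
    sig = raw.get_data() * 1e6  # mne returns volts
    trials = []
    for onset in onsets:
        c = int(round(onset * sfreq))
        if c + n_lo < 0 or c + n_hi > sig.shape[1]:
            raise ParseError(f"annotation at {onset:.3f} s exceeds the recording")
        trials.append(sig[:, c + n_lo:c + n_hi])
    data = np.stack(trials)
    times = (np.arange(n_lo, n_hi)) / sfreq

    meta = read_metadata(metadata_sidecar_path(path))
    if len(meta) != data.shape[0]:
        raise AlignmentError(
            f"{len(meta)} metadata rows vs {data.shape[0]} annotated trials in {path.name}")
    return TrialEpochs(data, sfreq, times, montage, meta, unit="volts_uV")


def read_epochs(path: str | Path, format: str = "container",
                tmin: float = -0.5, tmax: float = 3.8,
                head_radius: float = 10.0,
                return_baseline: bool = False):
    """Read validated epochs from ``container``, ``edf`` or ``brainvision`` files.

    For the raw formats, epochs are cut around each ``trial`` annotation over
    the half-open window [tmin, tmax) and metadata is read from the TSV
    sidecar. Raises :class:`AlignmentError` when sidecar rows do not match the
    epoch count and :class:`ParseError` for malformed files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "container":
        epochs, baseline = _read_container(path)
    elif format in ("edf", "brainvision"):
        epochs = _read_raw_epochs(path, format, tmin, tmax, head_radius)
        baseline = None
    else:
        raise ValueError(f"unknown format '{format}'")
    issues = validate_epochs(epochs)
    if issues:
        raise ParseError(f"{path.name}: invalid epochs: " + "; ".join(issues))
    return (epochs, baseline) if return_baseline else epochs


# ---------------------------------------------------------------------------
# Clinical scores

def write_clinical_scores(scores: ClinicalScores, path: str | Path) -> None:
    scores.table.to_csv(path, sep="\t", index_label="subject", na_rep="n/a")


def read_clinical_scores(path: str | Path) -> ClinicalScores:
    table = pd.read_csv(path, sep="\t", index_col="subject", na_values=["n/a"])
    return ClinicalScores(table)
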