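"""Morlet time-frequency power and narrowband phase/amplitude extraction.

Power is the squared magnitude of the convolution with a complex Morlet
wavelet (default 5 cycles) per trial, channel and frequency, expressed either
raw (uV^2, or (uV/cm^2)^2 after CSD) or in dB relative to the mean power of
the resting baseline segments: dB = 10*log10(power / baseline mean), with the
baseline pooled across blocks by default.

Edge handling: each epoch's first and last two wavelet standard deviations
(2 * n_cycles / (2*pi*f) seconds, frequency dependent) are marked invalid in
:attr:`TFPower.valid`; downstream statistics exclude those bins.

For phase-amplitude coupling, narrowband phase and amplitude come from a
zero-phase windowed-sinc FIR band-pass followed by the Hilbert analytic
signal. The FIR order targets a 0.5 Hz transition band but is capped so the
filter (and the forward-backward padding) fits inside a single epoch; on the
default 4.3 s epochs the effective transition is therefore wider than the
target (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import BaselineSegments, TrialEpochs

__all__ = ["TFPower", "PhaseAmpSeries", "morlet_tfr", "db_baseline",
           "narrowband_phase_amplitude", "default_glm_freqs"]


def default_glm_freqs() -> np.ndarray:
    """Default GLM frequency grid, 2-40 Hz in 1 Hz steps.

    The grid covers the 4-15 Hz range where load and success effects are
    expected, with margin; 1 Hz is excluded because a 5-cycle wavelet at
    1 Hz does not fit inside a [-0.5, 3.8) s epoch.
    """
    return np.arange(2.0, 41.0)


@dataclass
class TFPower:
    """trials x channels x frequencies x times power with axis metadata."""

    data: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    sfreq: float
    unit: str = "raw"                       # "raw" | "dB_vs_baseline"
    baseline: str = ""
    valid: np.ndarray = None                # (freqs, times) edge mask

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones((len(self.freqs), len(self.times)), bool)
        if np.any(np.diff(self.freqs) <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("frequency and time axes must be increasing")
        if self.unit == "raw" and np.any(self.data < 0):
            raise ValueError("raw power must be nonnegative")

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)

    def pick_channels(self, names: list[str]) -> "TFPower":
        idx = [self.channel_index(n) for n in names]
        return TFPower(self.data[:, idx], self.freqs, self.times,
                       tuple(names), self.sfreq, self.unit, self.baseline,
                       self.valid)


def _edge_valid_mask(freqs: np.ndarray, times: np.ndarray,
                     n_cycles: float) -> np.ndarray:
    """True where a bin is >= 2 wavelet standard deviations from both edges."""
    sigma_t = n_cycles / (2.0 * np.pi * freqs)
    lo = times[0] + 2.0 * sigma_t
    hi = times[-1] - 2.0 * sigma_t
    return (times[None, :] >= lo[:, None]) & (times[None, :] <= hi[:, None])


def _check_wavelet_fits(freqs: np.ndarray, n_cycles: float, sfreq: float,
                        n_samples: int) -> None:
    # the wavelet support spans 10 standard deviations (5 on each side)
    length = np.ceil(10.0 * n_cycles / (2.0 * np.pi * freqs) * sfreq)
    too_long = freqs[length > n_samples]
    if too_long.size:
        raise ValueError(
            f"wavelet longer than epoch at {too_long.min():g} Hz; "
            "raise the lowest frequency or reduce n_cycles")


def morlet_tfr(epochs: TrialEpochs, freqs=None, n_cycles: float = 5.0,
               decim: int = 1, channels: list[str] | None = None) -> TFPower:
    """Raw Morlet power of epoched data (trials x channels x freqs x times)."""
    freqs = np.asarray(freqs if freqs is not None else default_glm_freqs(),
                       float)
    if np.any(freqs >= epochs.sfreq / 2):
        raise ValueError("all frequencies must be below Nyquist")
    data = epochs.data
    names = list(epochs.montage.names)
    if channels is not None:
        idx = [epochs.channel_index(c) for c in channels]
        data = data[:, idx]
        names = list(channels)
    _check_wavelet_fits(freqs, n_cycles, epochs.sfreq, data.shape[-1])
    from mne.time_frequency import tfr_array_morlet

    power = tfr_array_morlet(data, epochs.sfreq, freqs, n_cycles=n_cycles,
                             output="power", decim=decim, verbose="error")
    times = epochs.times[::decim]
    valid = _edge_valid_mask(freqs, times, n_cycles)
    return TFPower(power, freqs, times, tuple(names), epochs.sfreq / decim,
                   unit="raw",
                   valid=valid)


def baseline_power(baseline: BaselineSegments, freqs, channels_n: int,
                   n_cycles: float = 5.0, pooled: bool = True) -> np.ndarray:
    """Mean Morlet power of the resting segments, (channels, freqs).

    With ``pooled=True`` (default) the mean is taken across both blocks;
    otherwise an array (n_blocks, channels, freqs) is returned.
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = np.asarray(freqs, float)
    per_block = []
    for seg in baseline.segments:
        _check_wavelet_fits(freqs, n_cycles, baseline.sfreq, seg.shape[-1])
        p = tfr_array_morlet(seg[None], baseline.sfreq, freqs,
                             n_cycles=n_cycles, output="power",
                             verbose="error")[0]
        n_edge = int(np.ceil(2.0 * n_cycles / (2 * np.pi * freqs.min())
                             * baseline.sfreq))
        per_block.append(p[:, :, n_edge:p.shape[-1] - n_edge].mean(axis=-1))
    per_block = np.stack(per_block)
    return per_block.mean(axis=0) if pooled else per_block


def db_baseline(tfr: TFPower, baseline: BaselineSegments,
                n_cycles: float = 5.0, pooled: bool = True,
                trial_blocks=None) -> TFPower:
    """Convert raw power to dB relative to resting-baseline mean power.

    By default the baseline is pooled across both blocks. With
    ``pooled=False`` each trial is normalised by its own block's baseline;
    ``trial_blocks`` must then give the 1-based block index per trial.
    """
    if tfr.unit != "raw":
        raise ValueError("db_baseline expects raw power")
    base = baseline_power(baseline, tfr.freqs, len(tfr.channels),
                          n_cycles=n_cycles, pooled=pooled)
    if np.any(base <= 0):
        raise ValueError("baseline power is zero for some channel/frequency")
    if base.shape[-2] != tfr.data.shape[1]:
        raise ValueError("baseline channel count does not match the TFR")
    if pooled:
        db = 10.0 * np.log10(tfr.data / base[None, :, :, None])
        desc = "dB vs pooled 15 s resting blocks"
    else:
        if trial_blocks is None:
            raise ValueError("per-block baselining needs trial_blocks")
        blocks = np.asarray(trial_blocks, int) - 1
        if blocks.min() < 0 or blocks.max() >= base.shape[0]:
            raise ValueError("trial block index outside the baseline blocks")
        db = 10.0 * np.log10(tfr.data / base[blocks][:, :, :, None])
        desc = "dB vs own-block 15 s resting baseline"
    return TFPower(db, tfr.freqs, tfr.times, tfr.channels, tfr.sfreq,
                   unit="dB_vs_baseline", baseline=desc, valid=tfr.valid)


@dataclass
class PhaseAmpSeries:
    """Per-trial narrowband phase (rad) or amplitude envelope for one channel."""

    kind: str                       # "phase" | "amplitude"
    values: np.ndarray              # (n_trials, n_samples)
    center: float
    bandwidth: float
    times: np.ndarray
    sfreq: float
    channel: str
    unreliable: np.ndarray = field(default=None)  # per-trial flag

    def __post_init__(self) -> None:
        if self.unreliable is None:
            self.unreliable = np.zeros(self.values.shape[0], bool)


def _fir_bandpass(center: float, bandwidth: float, sfreq: float,
                  n_samples: int, transition: float = 0.5) -> np.ndarray:
    lo = center - bandwidth / 2.0
    hi = center + bandwidth / 2.0
    ntaps = int(np.ceil(3.3 / transition * sfreq))
    ntaps = min(ntaps, max(33, (n_samples - 2) // 3 * 2 - 1))
    ntaps += 1 - ntaps % 2  # odd
    return sps.firwin(ntaps, [lo, hi], pass_zero=False, fs=sfreq,
                      window="hamming")


def narrowband_phase_amplitude(epochs: TrialEpochs, channel: str,
                               center: float, bandwidth: float,
                               kind: str) -> PhaseAmpSeries:
    """Zero-phase FIR band-pass + Hilbert phase or amplitude for one channel.

    Phase is wrapped to (-pi, pi]; amplitude is the analytic-signal modulus.
    Trials whose envelope is numerically zero are flagged unreliable (their
    phase is defined but meaningless).
    """
    nyq = epochs.sfreq / 2.0
    lo, hi = center - bandwidth / 2.0, center + bandwidth / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {lo:g}-{hi:g} Hz outside (0, Nyquist)")
    duration = epochs.n_samples / epochs.sfreq
    if bandwidth < 2.0 / duration:
        raise ValueError(
            f"band of {bandwidth:g} Hz too narrow for a {duration:g} s epoch")
    if kind not in ("phase", "amplitude"):
        raise ValueError("kind must be 'phase' or 'amplitude'")
    x = epochs.get_channel(channel)
    taps = _fir_bandpass(center, bandwidth, epochs.sfreq, epochs.n_samples)
    # forward-backward FIR == single pass with the (symmetric, zero-phase)
    # autocorrelation kernel; FFT convolution keeps the grid loops fast
    kernel = np.convolve(taps, taps[::-1])
    xf = sps.fftconvolve(x, kernel[None, :], mode="same", axes=-1)
    analytic = sps.hilbert(xf, axis=-1)
    env = np.abs(analytic)
    unreliable = env.max(axis=-1) < 1e-12 * max(1.0, np.abs(x).max())
    values = np.angle(analytic) if kind == "phase" else env
    if kind == "phase":
        # angle returns [-pi, pi]; map -pi to +pi for the (-pi, pi] convention
        values = np.where(values == -np.pi, np.pi, values)
    return PhaseAmpSeries(kind, values, center, bandwidth, epochs.times,
                          epochs.sfreq, channel, unreliable)
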