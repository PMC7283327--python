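"""Synthetic Sternberg-task EEG cohorts with a known, injectable effect structure.

The generator emulates a letter-scanning working-memory session: 270 trials
(90 per memory load 2/4/6) in 2 main blocks of 15 nine-trial sub-blocks, each
sub-block at a constant load. Epochs span [-0.5, 3.8) s around memory-set
onset (0-1.8 s encoding, 1.8-3.8 s maintenance) on a 40-channel montage over
spatially correlated 1/f background noise, plus a 15 s noise-only resting
segment per block for dB baselining.

Injected effects (all magnitudes configurable through :class:`EffectConfig`):

* load-scaled 6 Hz theta bursts on left temporoparietal channels
  (healthy-control-like subjects only; the MS-like group gets a flat,
  load-independent theta level);
* medial-frontal 6 Hz theta scaled by per-trial success (SMP) with a
  group-dependent sign (positive modulation for HC-like, negative for
  MS-like subjects);
* load-scaled occipital 10 Hz alpha suppression (HC-like only);
* frontal-theta-phase -> parietal-gamma-amplitude coupling at Fz->CP3 during
  maintenance with modulation depth kappa = kappa0 + kappa1 * SMP * ML
  (HC-like; zero depth for MS-like), and a weaker reverse parietal-phase ->
  frontal-beta coupling;
* lagged stochastic theta-band drives between Fz and CP3 giving directed,
  Granger-detectable coupling: Fz->CP3 weighted by ML*SMP and CP3->Fz
  weighted by SMP (HC-like only).

Behaviour: per-trial correctness is drawn from a logistic in memory load;
reaction times are log-normal per response category with slower errors; a
small fraction of trials has no response (SMP and RT missing).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    BaselineSegments,
    CLINICAL_TESTS,
    ClinicalScores,
    LEFT_TEMPOROPARIETAL,
    MEDIAL_FRONTAL,
    Montage,
    OCCIPITAL,
    TrialEpochs,
    make_metadata,
    standard_montage,
)

__all__ = [
    "EffectConfig", "ConfigurationError", "SubjectRecord",
    "make_task_schedule", "simulate_subject", "simulate_cohort",
    "iter_cohort", "draw_cohort_profile",
]

ENCODING = (0.0, 1.8)
MAINTENANCE = (1.8, 3.8)


class ConfigurationError(ValueError):
    """Raised for unstable or out-of-range effect configurations."""


@dataclass
class EffectConfig:
    """Effect magnitudes and behavioural parameters of the generator.

    Amplitudes are in uV, slopes in dB per memory-load item, coupling depths
    dimensionless in [0, 1). The defaults are synthetic choices sized so the
    injected effects are recoverable by the analysis stages at cohort sizes
    of ~20 subjects per group; they are not estimates of real effect sizes.
    """

    # oscillatory power effects
    theta_base_uv: float = 2.5
    theta_ml_db: float = 0.75          # left temporoparietal 6 Hz, dB/item
    frontal_theta_base_uv: float = 3.0
    frontal_theta_db: float = 2.5      # medial frontal 6 Hz, dB per SMP unit
    alpha_base_uv: float = 3.0
    alpha_ml_db: float = -0.5          # occipital 10 Hz, dB/item (<= 0)
    # phase-amplitude coupling (Fz theta phase -> CP3 gamma amplitude)
    gamma_base_uv: float = 4.0
    pac_kappa0: float = 0.3
    pac_kappa1: float = 0.08           # interaction slope on SMP*ML
    pac_phase0: float = 0.0            # preferred phase (rad)
    # reverse coupling (CP3 theta phase -> Fz beta amplitude)
    beta_base_uv: float = 1.0
    pac_rev_kappa0: float = 0.2
    pac_rev_kappa1: float = 0.0
    # directed lagged coupling (Granger-detectable)
    gc_drive_uv: float = 6.0
    gc_fp: float = 0.8                 # Fz->CP3 weight, scaled by (ML/6)*SMP
    gc_pf: float = 0.8                 # CP3->Fz weight, scaled by SMP
    gc_lag_s: float = 0.01
    # behaviour
    acc_intercept: float = 3.5
    acc_slope: float = -0.26           # logit units per item
    rt_medians: dict = field(default_factory=lambda: {
        "CM": 0.75, "CnM": 0.80, "EM": 1.00, "EnM": 0.95})
    rt_sigma: float = 0.25
    p_no_response: float = 0.01
    # background noise
    noise_uv: float = 10.0
    noise_exponent: float = 1.0
    spatial_sigma: float = 0.35        # chordal mixing scale on the unit sphere
    # optional blink artifacts
    blink_rate: float = 0.0            # per-trial probability
    blink_uv: float = 150.0
    blink_dur_s: float = 0.2
    # between-subject variability and clinical linkage
    subject_sd: float = 0.3            # lognormal sd of per-subject effect scales
    pasat_coupling_rho: float = 0.6    # corr(PASAT, injected Fz->CP3 weight)

    def validate(self) -> None:
        kmax = self.pac_kappa0 + max(0.0, self.pac_kappa1) * 6
        krev = self.pac_rev_kappa0 + max(0.0, self.pac_rev_kappa1) * 6
        if not (0 <= self.pac_kappa0 < 1 and kmax < 1 and 0 <= krev < 1):
            raise ConfigurationError("PAC modulation depth must stay in [0, 1)")
        # worst-case bidirectional gain; the lagged loop must be contractive
        if np.sqrt(abs(self.gc_fp * self.gc_pf)) >= 1.0:
            raise ConfigurationError(
                "AR coupling weights unstable: sqrt(|c_fp*c_pf|) >= 1")
        if self.alpha_ml_db > 0:
            raise ConfigurationError("alpha load slope must be <= 0")

    @classmethod
    def null(cls) -> "EffectConfig":
        """Noise-only configuration: every injected effect switched off."""
        return cls(theta_base_uv=0.0, frontal_theta_base_uv=0.0,
                   alpha_base_uv=0.0, gamma_base_uv=0.0, beta_base_uv=0.0,
                   gc_drive_uv=0.0, gc_fp=0.0, gc_pf=0.0,
                   pac_kappa0=0.0, pac_kappa1=0.0, pac_rev_kappa0=0.0,
                   blink_rate=0.0, pasat_coupling_rho=0.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EffectConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# Task schedule

def make_task_schedule(seed: int) -> pd.DataFrame:
    """Random session schedule: 2 blocks x 15 sub-blocks x 9 same-load trials.

    Loads are balanced (90 trials each of 2, 4, 6 items; 5 sub-blocks per
    load per block) with sub-block order randomised; probe match is drawn
    50/50 per trial and the response hand alternates across sub-blocks.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for block in (1, 2):
        loads = np.repeat([2, 4, 6], 5)
        rng.shuffle(loads)
        for sb, ml in enumerate(loads, start=1):
            hand = "right" if (sb + 15 * (block - 1)) % 2 == 1 else "left"
            for _ in range(9):
                rows.append((block, sb, int(ml),
                             "match" if rng.random() < 0.5 else "nonmatch",
                             hand))
    sched = pd.DataFrame(rows, columns=["block", "sub_block", "ml", "match", "hand"])
    return sched


# ---------------------------------------------------------------------------
# Subject simulation

def _shaped_noise(rng: np.random.Generator, shape: tuple, sfreq: float,
                  exponent: float) -> np.ndarray:
    """1/f^exponent Gaussian noise along the last axis, unit variance."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal(shape[:-1] + (len(freqs),))
            + 1j * rng.standard_normal(shape[:-1] + (len(freqs),))) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std()
    return x / sd if sd > 0 else x


def _mixing_matrix(montage: Montage, spatial_sigma: float) -> np.ndarray:
    """Cholesky factor of a distance-decaying channel correlation matrix."""
    pos = montage.positions
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    corr = np.exp(-d2 / (2.0 * spatial_sigma ** 2))
    return np.linalg.cholesky(corr + 1e-9 * np.eye(len(corr)))


def _ramp_window(times: np.ndarray, t0: float, t1: float,
                 ramp: float = 0.2) -> np.ndarray:
    """Unit window over [t0, t1) with raised-cosine on/off ramps."""
    w = np.zeros_like(times)
    inside = (times >= t0) & (times < t1)
    w[inside] = 1.0
    up = inside & (times < t0 + ramp)
    w[up] = 0.5 * (1 - np.cos(np.pi * (times[up] - t0) / ramp))
    dn = inside & (times >= t1 - ramp)
    w[dn] = 0.5 * (1 - np.cos(np.pi * (t1 - times[dn]) / ramp))
    return w


def _band_drive(rng: np.random.Generator, n_trials: int, n_samp: int,
                sfreq: float, band=(2.0, 25.0)) -> np.ndarray:
    """Unit-variance stochastic band-limited drive per trial.

    The band is kept broad (default 2-25 Hz): the directed coupling is only
    Granger-detectable if the lagged copy carries innovations that the
    receiver cannot predict from its own past, and a very narrow band makes
    the drive self-predictable.
    """
    sos = sps.butter(2, list(band), btype="bandpass", fs=sfreq, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal((n_trials, n_samp)), axis=-1)
    sd = x.std()
    return x / sd if sd > 0 else x


def _delayed(x: np.ndarray, lag: int) -> np.ndarray:
    out = np.zeros_like(x)
    if lag < x.shape[-1]:
        out[..., lag:] = x[..., :x.shape[-1] - lag]
    return out


def _draw_behavior(rng: np.random.Generator, sched: pd.DataFrame,
                   effects: EffectConfig) -> pd.DataFrame:
    ml = sched["ml"].to_numpy()
    p_correct = 1.0 / (1.0 + np.exp(-(effects.acc_intercept + effects.acc_slope * ml)))
    smp = (rng.random(len(ml)) < p_correct).astype(float)
    no_resp = rng.random(len(ml)) < effects.p_no_response
    smp[no_resp] = np.nan
    cat = np.where(smp == 1,
                   np.where(sched["match"] == "match", "CM", "CnM"),
                   np.where(sched["match"] == "match", "EM", "EnM"))
    med = np.array([effects.rt_medians[c] for c in cat])
    rt = med * np.exp(effects.rt_sigma * rng.standard_normal(len(ml)))
    rt[no_resp] = np.nan
    meta = make_metadata(block=sched["block"], sub_block=sched["sub_block"],
                         ml=ml, match=sched["match"], smp=smp, rt=rt,
                         hand=sched["hand"])
    return meta


def simulate_subject(schedule: pd.DataFrame, effects: EffectConfig,
                     group: str = "HC", seed: int = 0, sfreq: float = 500.0,
                     montage: Montage | None = None,
                     return_truth: bool = False, subject_scale: float = 1.0):
    """Simulate one subject's epochs and per-block resting baselines.

    ``group`` selects the effect pattern: ``"HC"`` gets the full injected
    structure, ``"MS"`` gets flat (load-independent) theta/alpha, a negative
    frontal SMP modulation and no coupling. ``subject_scale`` multiplies the
    subject's coupling weights (between-subject variability; used by the
    cohort generator to anchor the clinical correlation).

    Returns ``(TrialEpochs, BaselineSegments)``; with ``return_truth=True`` a
    third dict records everything injected (blink trials, carrier phases,
    per-trial modulation depths and coupling weights, the stochastic drives),
    so tests can score recovery against ground truth.
    """
    if group not in ("HC", "MS"):
        raise ValueError("group must be 'HC' or 'MS'")
    effects.validate()
    rng = np.random.default_rng(seed)
    montage = montage if montage is not None else standard_montage()
    n_trials = len(schedule)
    n_lo = int(round(0.5 * sfreq))
    n_samp = n_lo + int(round(3.8 * sfreq))
    times = (np.arange(n_samp) - n_lo) / sfreq
    names = list(montage.names)

    meta = _draw_behavior(rng, schedule, effects)
    ml = meta["ml"].to_numpy(dtype=float)
    smp = np.nan_to_num(meta["smp"].to_numpy(dtype=float))  # no-response -> 0

    mix = _mixing_matrix(montage, effects.spatial_sigma)
    noise = _shaped_noise(rng, (n_trials, len(names), n_samp), sfreq,
                          effects.noise_exponent)
    data = effects.noise_uv * np.einsum("ck,tks->tcs", mix, noise)

    hc = group == "HC"
    truth: dict = {"group": group, "subject_scale": subject_scale}

    def db_amp(base: float, slope_db: float, x: np.ndarray) -> np.ndarray:
        return base * 10.0 ** (slope_db * x / 20.0)

    # --- left temporoparietal theta (6 Hz), load-scaled for HC
    phi_p = rng.uniform(-np.pi, np.pi, n_trials)
    a_tp = db_amp(effects.theta_base_uv, effects.theta_ml_db,
                  ml if hc else np.full(n_trials, 4.0))
    w_task = _ramp_window(times, 0.0, 3.8)
    theta_p = (a_tp[:, None] * w_task
               * np.cos(2 * np.pi * 6.0 * times + phi_p[:, None]))
    for name in LEFT_TEMPOROPARIETAL:
        data[:, montage.index(name), :] += theta_p

    # --- medial frontal theta (6 Hz), SMP-scaled with group-dependent sign
    phi_f = rng.uniform(-np.pi, np.pi, n_trials)
    sign = 1.0 if hc else -1.0
    a_mf = db_amp(effects.frontal_theta_base_uv,
                  sign * effects.frontal_theta_db, smp)
    w_maint = _ramp_window(times, *MAINTENANCE)
    theta_f = (a_mf[:, None] * w_maint
               * np.cos(2 * np.pi * 6.0 * times + phi_f[:, None]))
    for name in MEDIAL_FRONTAL:
        data[:, montage.index(name), :] += theta_f

    # --- occipital alpha (10 Hz), negative load scaling for HC
    a_al = db_amp(effects.alpha_base_uv, effects.alpha_ml_db,
                  ml if hc else np.full(n_trials, 4.0))
    w_alpha = _ramp_window(times, 0.5, 2.5)
    alpha = (a_al[:, None] * w_alpha
             * np.cos(2 * np.pi * 10.0 * times
                      + rng.uniform(-np.pi, np.pi, n_trials)[:, None]))
    for name in OCCIPITAL:
        data[:, montage.index(name), :] += alpha

    # --- Fz theta phase -> CP3 gamma amplitude (40 Hz) during maintenance
    kappa = np.zeros(n_trials)
    if hc:
        kappa = np.clip(effects.pac_kappa0 + effects.pac_kappa1 * smp * ml,
                        0.0, 0.95)
    phase_f = 2 * np.pi * 6.0 * times[None, :] + phi_f[:, None]
    modulator = 1.0 + kappa[:, None] * np.cos(phase_f - effects.pac_phase0)
    gamma = (effects.gamma_base_uv * modulator * w_maint
             * np.cos(2 * np.pi * 40.0 * times
                      + rng.uniform(-np.pi, np.pi, n_trials)[:, None]))
    data[:, montage.index("CP3"), :] += gamma

    # --- CP3 theta phase -> Fz beta amplitude (20 Hz), reverse direction
    kap_r = np.zeros(n_trials)
    if hc:
        kap_r = np.clip(effects.pac_rev_kappa0
                        + effects.pac_rev_kappa1 * smp * ml, 0.0, 0.95)
    phase_p = 2 * np.pi * 6.0 * times[None, :] + phi_p[:, None]
    beta = (effects.beta_base_uv
            * (1.0 + kap_r[:, None] * np.cos(phase_p - effects.pac_phase0))
            * w_maint
            * np.cos(2 * np.pi * 20.0 * times
                     + rng.uniform(-np.pi, np.pi, n_trials)[:, None]))
    data[:, montage.index("Fz"), :] += beta

    # --- lagged stochastic drives: directed, Granger-detectable coupling
    lag = int(round(effects.gc_lag_s * sfreq))
    drive_f = _band_drive(rng, n_trials, n_samp, sfreq)
    drive_p = _band_drive(rng, n_trials, n_samp, sfreq)
    w_fp = (subject_scale * effects.gc_fp * (ml / 6.0) * smp) if hc \
        else np.zeros(n_trials)
    w_pf = (subject_scale * effects.gc_pf * smp) if hc else np.zeros(n_trials)
    amp_d = effects.gc_drive_uv
    data[:, montage.index("Fz"), :] += amp_d * w_maint * drive_f
    data[:, montage.index("CP3"), :] += amp_d * w_maint * drive_p
    data[:, montage.index("CP3"), :] += (
        amp_d * w_fp[:, None] * w_maint * _delayed(drive_f, lag))
    data[:, montage.index("Fz"), :] += (
        amp_d * w_pf[:, None] * w_maint * _delayed(drive_p, lag))

    # --- optional stereotyped blinks on prefrontal channels
    blink_trials = np.array([], dtype=int)
    if effects.blink_rate > 0:
        blink_trials = np.flatnonzero(rng.random(n_trials) < effects.blink_rate)
        n_blink = int(round(effects.blink_dur_s * sfreq))
        pulse = effects.blink_uv * np.hanning(n_blink)
        weights = {"Fp1": 1.0, "Fp2": 1.0, "AFz": 0.8, "F3": 0.4, "Fz": 0.4,
                   "F4": 0.4}
        for t in blink_trials:
            start = rng.integers(0, n_samp - n_blink)
            for name, w in weights.items():
                if name in names:
                    data[t, montage.index(name), start:start + n_blink] += w * pulse
    truth.update(blink_trials=blink_trials, phi_frontal=phi_f,
                 phi_parietal=phi_p, kappa=kappa, kappa_rev=kap_r,
                 w_fp=w_fp, w_pf=w_pf, gamma_modulator=modulator,
                 drive_frontal=drive_f, drive_parietal=drive_p,
                 theta_amp_tp=a_tp, alpha_amp=a_al)

    epochs = TrialEpochs(data, sfreq, times, montage, meta, unit="volts_uV")

    n_base = int(round(15.0 * sfreq))
    segs = []
    for _ in range(2):
        bn = _shaped_noise(rng, (1, len(names), n_base), sfreq,
                           effects.noise_exponent)[0]
        segs.append(effects.noise_uv * (mix @ bn))
    baseline = BaselineSegments(segs, sfreq)

    if return_truth:
        return epochs, baseline, truth
    return epochs, baseline


# ---------------------------------------------------------------------------
# Cohorts

@dataclass
class SubjectRecord:
    subject: str
    group: str
    epochs: TrialEpochs
    baseline: BaselineSegments
    clinical: pd.Series
    truth: dict


def draw_cohort_profile(n_per_group: int, effects: EffectConfig,
                        seed: int) -> pd.DataFrame:
    """Per-subject design table: group, seeds, effect scale, clinical scores.

    The PASAT z-score is generated with correlation
    ``effects.pasat_coupling_rho`` to the subject's injected Fz->CP3
    interaction weight (on the log scale); the remaining tests are
    independent standard normals. Deterministic given ``seed``.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    subjects = [f"HC{i:02d}" for i in range(n_per_group)] + \
               [f"MS{i:02d}" for i in range(n_per_group)]
    groups = ["HC"] * n_per_group + ["MS"] * n_per_group
    n = len(subjects)
    log_scale = effects.subject_sd * rng.standard_normal(n)
    scale = np.exp(log_scale)
    rho = float(np.clip(effects.pasat_coupling_rho, -1.0, 1.0))
    z = (log_scale / effects.subject_sd) if effects.subject_sd > 0 \
        else rng.standard_normal(n)
    pasat = rho * z + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)
    prof = pd.DataFrame({
        "subject": subjects, "group": groups,
        "seed": rng.integers(0, 2 ** 31 - 1, n),
        "scale": scale,
        "w_fp_subject": effects.gc_fp * scale,
        "pasat": pasat,
    }).set_index("subject")
    for test in CLINICAL_TESTS[1:]:
        prof[test] = rng.standard_normal(n)
    return prof


def iter_cohort(n_per_group: int, effects: EffectConfig | None = None,
                seed: int = 0, sfreq: float = 500.0,
                montage: Montage | None = None, return_truth: bool = True):
    """Lazily yield :class:`SubjectRecord` for a two-group cohort."""
    effects = effects if effects is not None else EffectConfig()
    montage = montage if montage is not None else standard_montage()
    prof = draw_cohort_profile(n_per_group, effects, seed)
    for subject, row in prof.iterrows():
        schedule = make_task_schedule(int(row["seed"]) % (2 ** 31 - 1))
        epochs, baseline, truth = simulate_subject(
            schedule, effects, group=row["group"], seed=int(row["seed"]),
            sfreq=sfreq, montage=montage, return_truth=True,
            subject_scale=float(row["scale"]))
        clinical = row[["pasat", "sdmt", "bvmt", "avlt", "stroop"]].astype(float)
        clinical["group"] = row["group"]
        yield SubjectRecord(str(subject), str(row["group"]), epochs, baseline,
                            clinical if return_truth else clinical, truth)


def simulate_cohort(n_per_group: int, effects: EffectConfig | None = None,
                    seed: int = 0, **kwargs) -> list[SubjectRecord]:
    """Materialise :func:`iter_cohort` as a list (memory scales with n)."""
    return list(iter_cohort(n_per_group, effects, seed, **kwargs))


def cohort_clinical_scores(prof: pd.DataFrame) -> ClinicalScores:
    table = prof[["group"] + CLINICAL_TESTS].copy()
    return ClinicalScores(table)
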