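# Methods

`wmosc` analyses Sternberg-task EEG for working-memory oscillatory effects:
a single-trial general linear model of time-frequency power, nonparametric
group statistics with cluster-based permutation correction, and trial-level
directed (Granger) and cross-frequency (phase-amplitude) coupling between a
frontal and a left parietal electrode. Because no public recording of the
target experiment exists, the package ships a synthetic cohort generator
that reproduces the task design and the qualitative effect structure; every
stage is validated end-to-end against what the generator injected.

## Task and data model

A session is 270 trials — 90 per memory load of 2, 4 or 6 consonants — in
2 main blocks of 15 nine-trial sub-blocks, each sub-block at one load, order
randomised. Epochs span [-0.5, 3.8) s around memory-set onset (0–1.8 s
encoding, 1.8–3.8 s maintenance) on a 40-channel extended 10-20 montage;
each block contributes a 15 s resting segment for baselining. Trial
metadata: memory load ML ∈ {2,4,6}; success SMP ∈ {0,1} (missing when no
response was given — never coded 0); match flag; reaction time (s, missing
allowed); response hand; block indices. Times are seconds relative to
memory-set onset, sample indices 0-based, windows half-open [t0, t1).

## Preprocessing

* **Band-pass** 0.1–100 Hz, zero-phase order-4 Butterworth applied
  forward-backward. The 0.1 Hz high-pass has a ~10 s impulse response, so on
  a 4.3 s epoch a slow edge transient is unavoidable; even-reflection
  padding over the full epoch keeps the mid-epoch gain error at ~0.1%.
  Strict passband idempotence (≤1e-6) holds once the data are long enough
  for the transient to decay and is tested at that length.
* **Artifact rejection**: a trial is dropped when any channel sample exceeds
  ±100 µV (configurable); the retained count is reported per subject. Blink
  removal by ICA is delegated to external tooling — the generator's optional
  stereotyped blinks (150 µV, 200 ms, prefrontal) exceed the threshold and
  are caught by rejection.
* **Current source density**: spherical-spline surface Laplacian. The
  interpolation matrix uses g(x) = (1/4π) Σₙ (2n+1)/(n(n+1))ᵐ Pₙ(x) and the
  Laplacian matrix the companion series with exponent m−1; spline weights
  solve (G + λI)c = V under a zero-sum constraint and CSD = Hc/r². Defaults
  m = 4, λ = 1e-5, 50 Legendre terms, head radius 10 cm (the established
  defaults of the toolbox family for this transform; the analysis this
  package reproduces states none). On a dense test montage the CSD of a
  degree-1 spherical harmonic recovers the analytic eigenvalue n(n+1)/r²
  within 0.1%. The output has zero spatial mean only when electrodes sample
  the whole sphere; on a scalp cap the discrete mean is a few percent of
  signal scale, which is expected, not an error.

## Spectral estimation

Morlet wavelets (5 cycles) give per-trial power; the default GLM grid is
2–40 Hz in 1 Hz steps (a 5-cycle wavelet at 1 Hz does not fit the epoch).
Bins within 2 wavelet standard deviations of an epoch edge are flagged
invalid and excluded from statistics. Power is expressed in dB against the
mean Morlet power of the resting segments, pooled across both blocks by
default (per-block baselining is available by flag). Induced power is
computed per trial without subtracting the evoked mean.

Narrowband phase and amplitude for coupling analyses come from a zero-phase
windowed-sinc FIR band-pass followed by the Hilbert analytic signal. The
design targets a 0.5 Hz transition, which at 500 Hz would need ~3300 taps —
more than an epoch supports — so the order is capped to fit the epoch and
the effective transition widens to roughly 1.5–2.5 Hz. The forward-backward
pass is applied as a single convolution with the filter's autocorrelation
kernel (identical zero-phase response, much faster over PAC grids).

## First-level GLM and group statistics

Per subject, ordinary least squares of dB power on [1, ML, SMP] at every
(channel, frequency, time) bin, ML entering with raw item counts and SMP as
0/1; no-response trials are excluded. Regressors constant in the usable
trials are flagged undefined rather than NaN-propagated, and perfect fits
return exact slopes with unbounded t flagged separately.

Second level: Wilcoxon signed-rank (subject t-values vs zero, within group)
or rank-sum (between groups) per bin, with exact null distributions for
n ≤ 25 tie-free samples and a tie- and continuity-corrected normal
approximation otherwise.

Cluster-based permutation: bins with second-level p below 0.05 (two-sided)
are grouped into same-sign clusters — 4-connectivity over the
time-frequency plane per electrode by default, with an optional mode that
additionally bridges montage-neighbouring channels at the same bin (the
source analysis reports per-electrode charts; cross-electrode clustering is
not asserted). Cluster mass is the sum of signed standardized statistics;
the null of the maximal |mass| is built from 1000 sign-flips of subjects
(within) or group-label shuffles (between), the signed-rank statistic being
recomputed for every permutation from the (flip-invariant) ranks, so the
permutation loop is two matrix products plus labelling. Cluster
p = (1 + #{perm ≥ observed})/(n_perm + 1) and can never fall below
1/(n_perm+1). Measured family-wise error on 200 null datasets: 0.045 at
nominal 0.05.

## Coupling

**Granger causality.** Per trial and window (maintenance 1.8–3.8 s by
default, encoding available), a bivariate AR model on the CSD signals of Fz
and CP3, order selected by BIC up to a cap (default cap 20; the pipeline
uses 10 for speed; a fixed-order mode exists for strict reproducibility).
GC(x→y) = ln(σ²_y|own past / σ²_y|both pasts) ≥ 0 by nesting; the modeled
outcome is ΔGC = GC(F→P) − GC(P→F), positive meaning frontal-to-parietal
dominance, matching the sign convention of the study's connectivity table.
Degenerate fits flag the trial and exclude it from modeling.

**Phase-amplitude coupling.** For each (low, high) grid pair, the
circular-linear correlation between low-band phase (first channel) and
high-band amplitude (second channel) over the maintenance window,
r² = (r²_ca + r²_sa − 2 r_ca r_sa r_cs)/(1 − r²_cs). Filtering runs on the
whole epoch, then crops, to keep transients out of the window. The
reference grid is 1–35 Hz phase (0.4 Hz steps, 0.8 Hz bands) × 5–120 Hz
amplitude (1 Hz steps, 5 Hz bands) — 86 × 116 pairs. Note a physical
constraint: amplitude modulation at phase frequency f puts sidebands at
carrier ± f, so a 5 Hz-wide amplitude band cannot carry theta-rate
modulation; the reduced 8 × 12 grid the pipeline and tests use therefore
takes a 14 Hz amplitude bandwidth, which is what makes 6 Hz → 40 Hz
coupling detectable at all. The per-trial coefficient also carries a
positive small-sample bias that grows toward slow phase frequencies
(autocorrelated envelopes leave few effective samples); the bias is common
to all trials and groups, so the trial-level regression and between-group
contrasts — the ways the maps are actually used — are unaffected.

**Trial models and group tests.** Per subject, OLS of the per-trial value
(ΔGC scalar, or each PAC grid pair) on [1, ML, SMP, SMP·ML]; at the group
level the regressor t-values are tested with signed-rank (within) and
rank-sum (between), Bonferroni over the four regressors for GC, and with
the cluster permutation over the frequency-pair grid for PAC maps (initial
threshold 0.05, final cluster threshold 0.01).

## Behaviour and clinical linkage

Accuracy per load is tested against chance 0.5 (one-sided signed-rank
across subjects, Bonferroni over the three loads) and between groups per
load; the load-2-minus-load-6 drop is reported per subject. Reaction times
at load 6 use the per-subject median in the CM/CnM/EM/EnM categories
(medians, since all tests are nonparametric), with paired correct-vs-error
tests and two load-2 motor controls (correct−error RT difference,
right−left hand difference). The clinical stage computes Spearman
correlations between a per-subject coupling score — the t-value of the
load-by-success interaction from the ΔGC model — and each neuropsychological
z-score (PASAT, SDMT, BVMT-R, AVLT, Stroop), Bonferroni-corrected by the
number of tests supplied.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, over
spatially correlated 1/f background noise (exponent 1, 10 µV, Gaussian
distance-decaying channel mixing), at 500 Hz by default (Nyquist comfortably
above the 120 Hz analysis ceiling; 1 kHz available):

* load-scaled 6 Hz theta on left temporoparietal channels, 0.75 dB per item
  (HC-like groups only; MS-like subjects get a flat mid-load level);
* medial-frontal 6 Hz theta scaled by per-trial success, 2.5 dB per SMP
  unit on a 3 µV base, positive-signed for HC-like and negative for MS-like
  subjects;
* occipital 10 Hz alpha with a −0.5 dB/item load slope (HC-like only);
* Fz-theta-phase → CP3-gamma-amplitude coupling during maintenance with
  modulation depth κ = κ0 + κ1·SMP·ML (κ0 = 0.3, κ1 = 0.08, 4 µV gamma;
  zero depth for MS-like), plus a weaker reverse parietal-phase →
  frontal-beta coupling;
* directed lagged coupling via broadband (2–25 Hz) unit-variance stochastic
  drives, 6 µV, 10 ms lag: Fz→CP3 weighted by c_fp·(ML/6)·SMP and CP3→Fz by
  c_pf·SMP (c = 0.8, HC-like only). The drive must be broadband: a narrow
  band is nearly self-predictable and carries almost no Granger-detectable
  innovation. Configurations are rejected when √(c_fp·c_pf) ≥ 1 or any
  modulation depth leaves [0, 1).
* behaviour: correctness from a logistic in load (intercept 3.5, slope
  −0.26 per item ≈ 95% at load 2, 87% at load 6), log-normal RTs per
  response category with slower errors, 1% no-response trials;
* cohorts: per-subject log-normal effect scales (sd 0.3); the PASAT z-score
  is generated with correlation 0.6 to the subject's injected Fz→CP3
  interaction weight, the other clinical scores are independent normals.

All effect magnitudes are synthetic design choices, not estimates of real
effect sizes: the source study reports no effects in dB or coupling-depth
units. They were calibrated once, at design time, so that each injected
effect is recovered by the corresponding analysis stage with high
probability at 8 subjects per group (and hence comfortably at the study's
20 per group), and then frozen. Passing tests therefore demonstrate that
the pipeline recovers effects of the injected form and sign at realistic
noise levels — they say nothing about artifacts, non-stationarity, volume
conduction beyond distance-mixing, or any other property of real EEG the
generator does not model (no lesion anatomy, no realistic head-model
mixing, no eye or muscle activity unless the stereotyped blinks are
switched on).

## Numerical and design choices

* Exact signed-rank / rank-sum null distributions are built by dynamic
  programming and cached; permutation statistics reuse rank tables rather
  than recomputing tests per bin.
* Undefined bins (rank-deficient designs, edge-invalid TF bins) are
  excluded from clustering rather than zero-filled.
* Every random stage takes an explicit seed; the pipeline run report
  records all parameters and artifact checksums, and a rerun from the same
  config is checksum-identical.
* Problem sizes in the shipped tests and the acceptance script are chosen
  for a desk-scale run: recovery uses 8 subjects per group with full
  270-trial, 40-channel, 500 Hz sessions, a 2–20 Hz GLM grid on the
  channels carrying injected effects, the reduced PAC grid, and a GC order
  cap of 10; null calibration uses 200 datasets of 12 subjects × 16 × 25
  bins at 1000 permutations.

## Known limitations

* EDF export quantises at 0.1 µV (16-bit); BrainVision is read-only.
* The Granger stage is bivariate time-domain only; no spectral, conditional
  or multivariate variants, and no alternative PAC estimators.
* The circular-linear coefficient's small-sample bias makes raw PAC map
  values incomparable across phase frequencies; only within-trial-design
  contrasts (the regression models) and group differences are
  interpretable.
* Second-level exactness degrades to a normal approximation in the presence
  of ties, which cannot occur for continuous data but can for constructed
  inputs.
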