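# Methods

`cagewave` analyzes paired single-channel neocortical EEG and home-cage
video (as DeepLabCut-style pose tables) from mice, with absence-epilepsy
models in mind: it detects and masks spike-wave discharges (SWDs), measures
band power and theta-gamma phase-amplitude coupling on the SWD-free signal,
stages sleep into EEG-only REM/NREM, classifies waking behavior from pose
kinematics, and reports bout metrics and per-stage seizure rates. Because
such datasets are rarely public, the package ships a synthetic paired
EEG + pose generator with ground truth; every stage of the pipeline is
validated against it.

## Signal model and conventions

All intervals are half-open `[t0, t1)` in seconds on the EEG session clock;
a time maps to a sample index as `floor(t * fs)`, so abutting bouts never
share a sample. The EEG is a single channel in microvolts. The simulator
defaults to `fs = 200 Hz` so that the 45 Hz upper band edge sits well below
Nyquist; `fs` is otherwise treated as data (EDF header or an explicit rate
for text input). Analysis bands are delta 2–5 Hz, theta 6–10 Hz, and slow
gamma 25–45 Hz; the 16–32 Hz band holds the spectral harmonic typical of
SWDs. Fast gamma (> 45 Hz) is out of scope at this sampling rate.

## SWD detection

Detection follows a supervised two-stage design:

1. **Spike detection.** The baseline is the mean absolute value of the
   mean-subtracted whole recording — the most literal reading of "average
   baseline voltage"; it deliberately includes high-amplitude epochs so the
   threshold is a property of the whole signal. Local extrema of either
   polarity with |amplitude| ≥ 2.5× baseline, separated by a 50 ms
   refractory period, are spikes.
2. **Candidate assembly.** Maximal spike runs with inter-spike gaps
   ≤ 0.3 s (slower than the 5 Hz lower bound with margin), at least 4
   spikes, and ≥ 0.6 s span become candidates, so a minimal 5 Hz discharge
   passes. Because background oscillation peaks (rectified delta or theta
   waves riding on noise) routinely cross a 2.5× threshold, a run is
   refined to its longest rhythmically regular stretch (max/min ISI ratio
   ≤ 1.5): SWD spiking is near-periodic while threshold crossings of
   background rhythms are an irregular subsample of their cycle grid.
   Without this refinement, detected onsets drift away from the true event
   by more than the half-second a reviewer would tolerate.
3. **Scoring.** Three bounded, gain-invariant features per candidate:
   * `f_freq` — 1 when the median instantaneous spike rate lies in
     5–10 Hz, decaying linearly to 0 over 2 Hz outside;
   * `f_harm` — event power in 16–32 Hz divided by event power in
     1–45 Hz (Hann periodogram of the event segment);
   * `f_sharp` — concentration of finest-scale Daubechies-4 wavelet detail
     energy within ±25 ms of spike peaks, rescaled against the window duty
     cycle so featureless background maps to ≈ 0 and perfectly
     spike-locked detail energy to 1. "D4" here is the classic 4-tap
     Daubechies filter (PyWavelets `db2`).

   The features combine through a logistic score; weights, bias and the
   decision threshold can be calibrated against a hand-scored label table
   (L2-regularized logistic regression; threshold maximizing training
   balanced accuracy). The shipped defaults `w = (2, 4, 4)`, `b = −5`,
   `θ = 0.5` weight the harmonic and sharpness features more than spike
   frequency, because irregular noise crossings frequently mimic a 5–10 Hz
   rate but not the SWD spectrum or sharpness. Every candidate — accepted
   or not — is exported in a review table for manual verification.

Accepted events, dilated by 0.5 s, are removed before any spectral
analysis; remaining segments shorter than one analysis window are dropped,
and usable + excluded + dropped time exactly conserves the recording
duration.

## Spectra, band power, and PAC

PSDs are Welch estimates: 2 s Hann windows, 50 % overlap, averaged only
over windows lying wholly inside usable segments (no window straddles an
exclusion). 2 s windows give 0.5 Hz resolution, enough to resolve the
2 Hz-wide delta band. The density is normalized so its integral over
[0, fs/2] equals the signal variance (Parseval; verified to < 5 % on white
noise). Band power is the trapezoidal integral over the band with
interpolated edges. Per-bout band powers are computed on the bout minus SWD
exclusions; bouts with no usable window are skipped and counted.
Between-bout variability is summarized by percentile bootstrap CIs of the
mean (1000 resamples, seeded).

Phase-amplitude coupling uses the normalized Kullback–Leibler modulation
index: zero-phase 4th-order Butterworth bandpass (theta for phase, slow
gamma for amplitude), analytic signal via the Hilbert transform, 0.5 s
trimmed from each segment end against filter transients, mean amplitude in
18 phase bins normalized to a distribution, MI = KL(P‖uniform)/log(n bins)
∈ [0, 1] (empty bins are merged and the normalization adjusted). The null
is 200 circular time-shifts of the amplitude series (≥ 1 s), which
preserves both marginals while breaking the phase-amplitude relation;
coupling is significant when the observed MI exceeds the surrogate 95th
percentile. A diagnostic guards the classic theta-harmonic confound: it
flags the slow-gamma spectral peak as harmonic-suspect when its frequency
ratio to the theta peak is within 0.05 of an integer.

## Sleep staging and behavior classification

Sleep bouts are staged from the theta:delta band-power ratio in 5 s
epochs, computed on SWD-masked data and median-smoothed over 3 epochs.
Epochs fully masked by SWDs interpolate their ratio from neighboring
epochs — stages are locally persistent, whereas a bout-wide fill would mix
REM and NREM and systematically misstage event-containing epochs. The REM
threshold adapts per recording: the ratio distribution within sleep is
bimodal on a log scale (delta-dominant NREM vs theta-dominant REM), so the
threshold is the midpoint of a two-means split of log10(ratio); if the two
cluster means are closer than 0.6 decades the night is treated as unimodal
and a conservative mean + 1 SD (log scale) rule applies. A fixed-fraction
rule alone was rejected because its position relative to the REM mode
shifts with the REM fraction of the night. A fixed numeric threshold can
be passed instead. Stage runs are merged to ≥ 10 s (REM) / ≥ 15 s (NREM);
REM + NREM exactly partition staged sleep. Without EMG, REM here means
"EEG-only REM" — theta-dominant sleep, not atonia-confirmed REM.

Behavior is classified frame-wise from pose kinematics, then formed into
bouts that partition the usable track (precedence sleep > groom > dig >
walk > rest; sub-minimum runs merge into the longer neighbor):

* **sleep** — centroid speed < 0.5 cm/s and dispersion motion (rate of
  change of mean keypoint-to-centroid distance) < 0.3 cm/s, sustained
  ≥ 40 s — the standard video-sleep immobility convention;
* **walk** — speed ≥ 2 cm/s sustained ≥ 1 s;
* **groom** — slow centroid (< 1 cm/s) with 2–7 Hz head-relative
  oscillation ≥ 1.5 cm/s RMS while the snout is not below the body-center
  axis, ≥ 3 s;
* **dig** — slow centroid with 2–7 Hz vertical snout oscillation
  ≥ 1.5 cm/s while the snout is below the body-center axis, ≥ 3 s;
* **rest** — the awake residual.

Centroid positions are smoothed over 0.5 s *before* differentiation so
in-place oscillations (grooming, digging, tracking jitter) do not
masquerade as locomotion; dispersion motion is rectified before smoothing
so posture oscillation survives averaging. Low-likelihood pose frames
(< 0.9) are linearly interpolated and median-smoothed over 0.25 s; dropout
gaps > 1 s are flagged unusable. These kinematic signatures are
operational definitions chosen to be recoverable from the synthetic
generator; applying the classifier to real videos requires recalibrating
the thresholds against scored examples.

Hourly summaries count a bout once in the hour containing its onset while
splitting its occupied time across all hours it overlaps. A seizure belongs
to the stage containing its onset; per-stage rates are counts divided by
stage hours, with onsets outside any staged bout tallied as unstaged.

## The synthetic generator

The generator produces the statistical structure the analyses consume, not
biophysics: per state, a sum of three narrowband oscillators (delta, theta,
gamma) over 1/f pink noise (default σ = 15 µV). Band frequencies are
redrawn per bout (delta 2–5, theta 6–10, gamma 25–45 Hz) so band-power
estimation does not reduce to reading one spectral line, and every
oscillator carries a random-walk phase (0.8 rad/√s): real rhythms are not
phase-locked clocks, and — critically for the PAC null — a strictly
periodic modulator would make theta-gamma coupling invariant under
circular-shift surrogates. Gamma amplitude is modulated by theta phase as
`(1 + κ·cos φ_θ)/(1 + κ)` with depth κ ∈ [0, 1). State sequences come from
a semi-Markov scaffold (truncated-exponential dwells; defaults: sleep
400 s, rest 60 s, walk 30 s, groom/dig 40 s), sleep bouts alternate NREM
(mean 200 s) and REM (mean 90 s) segments, and state boundaries are
crossfaded over 0.25 s. Default band amplitudes (µV, delta/theta/gamma):
NREM 40/6/10, REM 4/30/10, rest 15/10/10, walk 6/25/10, groom and dig
8/15/10 — delta-dominant NREM, theta-dominant REM and locomotion, the
gamma amplitude equal across states within an animal. Genotype presets
scale gamma amplitude 1 : 1.5 : 2.25 (WT : HET : KO), the dosage pattern
under study, and give WT a zero SWD rate.

SWDs are Poisson per bout at stage-dependent rates (preset: REM 1.2/h,
NREM 0.1/h, waking 0.2–0.4/h), with uniform 1–4 s durations and a regular
spike train at 7 Hz (valid range 5–10 Hz). Each spike is one sharp
biphasic sine cycle of 20 ms half-width — sharp enough to concentrate
finest-scale D4 detail energy at the spikes, with harmonics of the 7 Hz
train falling in the 16–32 Hz band. Spike peak amplitude is 3× (config:
`swd_amp_mult`) the background's average baseline voltage, and the event
replaces the background with 0.1 s crossfades. True SWD amplitude relative
to background in vivo is not well characterized; the multiplier is a free
parameter swept in tests.

Pose tracks use five keypoints (snout, both ears, body center, tailbase)
in a 30 × 30 cm cage at 10 px/cm (a default recorded in the manifest — no
camera calibration is assumed) and 30 fps. Sleep is static with ~1 Hz
breathing micro-motion; rest drifts at 0.3 cm/s with a 0.5 Hz posture
(dispersion) oscillation; walking is a correlated random walk at
2.5–8 cm/s reflected at the walls; grooming and digging bob the head at
4 Hz along the snout axis, with the heading chosen so the snout sits above
(groom) or below (dig) the body-center axis. Smooth per-keypoint tracking
jitter (σ 0.03 cm) is added everywhere; likelihood dropout is configurable.

What the generator does *not* emulate — non-sinusoidal rhythm waveforms,
volume conduction, electrode drift, movement artifacts, multi-animal
occlusion, DLC identity swaps — bounds what passing tests show: they
validate the pipeline's logic and calibration under the stated statistical
structure, not performance on real recordings.

## Numerical choices and degenerate inputs

Deterministic seeding throughout (`numpy.random.default_rng`); the full
pipeline is byte-identical across reruns with the same seed. An
all-constant EEG yields baseline 0 and no spikes. A zero-delta window
returns an infinite ratio sentinel; a sleep bout shorter than one epoch is
staged NREM. Empty phase bins merge into neighbors. EDF output is 16-bit
with a symmetric physical range covering the data (round-trip error below
one quantization step) and pads partial final 1 s records. Events produced
by detection are validated never to overlap usable segments.

## Problem sizes in validation

The shipped acceptance runs use ten 1 h sessions at 20 SWDs/h for the
detector operating point, 50 short sessions for the PAC null calibration,
two 30 min sessions each for staging and behavior recovery, ten 8 h
sleep-heavy nights for per-stage seizure rates, and three genotypes × two
animals × 30 min for the dosage-ordering check. These sizes give each
estimate enough events for its comparison (e.g. ≈ 25–40 expected REM
seizures) while keeping the whole validation run around a minute on one
CPU.

## Known limitations

* The behavior and staging thresholds are calibrated to the generator's
  signatures; real-data use requires re-tuning and, for REM, EMG
  confirmation remains the gold standard.
* The detector's default weights are a design choice, not a reconstruction
  of any published weighting; fitting to hand-scored labels is the
  supported calibration path.
* Group-level inference (mixed models) is intentionally exported as tidy
  tables with hierarchical-bootstrap CIs rather than fitted internally.
* Single-channel analysis only; multi-channel EDF files are read through a
  channel selector.
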