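# cagewave

Analysis of paired single-channel neocortical EEG and home-cage video for
mouse epilepsy models: spike-wave discharge (SWD) detection and masking,
SWD-free band power and theta-gamma phase-amplitude coupling (PAC),
EEG-only REM/NREM sleep staging, pose-based behavior classification, and
per-stage seizure rates — plus a synthetic paired EEG + pose generator
with ground truth that makes the whole pipeline testable end to end.

## The problem

Absence-epilepsy models such as *Ank3-1b* knockout mice produce frequent
SWDs — rhythmic ~6–8 Hz sharp spike-and-wave complexes — that put
pronounced peaks into power spectra and must be removed before any
spectral claim. The scientific questions downstream are about oscillations
and state: is slow gamma (25–45 Hz) power elevated, and does it scale with
gene dosage? Is gamma amplitude coupled to theta phase, or merely a theta
harmonic? How is sleep architecture (REM vs NREM, by the theta 6–10 Hz to
delta 2–5 Hz power ratio) disturbed, and in which sleep stage do seizures
cluster? `cagewave` implements that entire chain as a reusable, seeded,
tested pipeline.

## Core methods

* **SWD detector** — spikes are local extrema ≥ 2.5× the average baseline
  voltage (mean |x − mean|) of the whole EEG; consecutive spikes form
  candidates, refined to their longest rhythmically regular stretch; each
  candidate is scored by a logistic model over three bounded features:
  spike rate in the 5–10 Hz range, the 16–32 Hz harmonic fraction of event
  power, and spike sharpness from finest-scale Daubechies-4 wavelet detail
  energy. The model can be fitted to hand-scored labels
  (`SWDDetector.fit`), and every candidate is exported for manual review.
  Accepted events are masked (±0.5 s) before all spectral analysis.
* **Spectra** — Welch PSD (2 s Hann windows, 50 % overlap) confined to
  usable segments, normalized so ∫PSD = variance; band power by
  trapezoidal integration; bout-level samples with bootstrap CIs; a
  harmonic diagnostic flags gamma peaks at integer multiples of theta.
* **PAC** — normalized Kullback–Leibler modulation index
  MI = KL(P‖uniform)/log 18 over phase-binned gamma amplitude, with a
  circular time-shift surrogate null (significant iff MI > surrogate 95th
  percentile).
* **Staging & behavior** — theta:delta ratio per 5 s epoch with an
  adaptive bimodal-split threshold stages sleep into EEG-only REM/NREM;
  a rule-based kinematic classifier labels sleep / rest / walk / groom /
  dig from DeepLabCut-style pose tables; hourly bout metrics and
  seizure-per-stage-hour rates close the loop.

See `docs/methods.md` for the full model description, parameter defaults,
and limitations.

## Worked example

Simulate a seizure-prone, theta-gamma-coupled session and run the whole
pipeline (also available as `cagewave run --out demo_out --seed 7`):

```python
import cagewave as cw

sim = cw.genotype_config("KO", session_s=3600.0)       # gamma-elevated preset
sim.kappa = 0.5                                        # theta-gamma coupling
sim.swd_rate_per_hour = {"REM": 12.0, "NREM": 1.0, "rest": 4.0,
                         "walk": 2.0, "groom": 2.0, "dig": 2.0}
manifest = cw.run_pipeline(cw.RunConfig(out_dir="demo_out", seed=7, sim=sim))
print(manifest["counts"])
```

```
{'n_swd_candidates': 407, 'n_swd_accepted': 5, 'usable_s': 3580.98,
 'n_behavior_bouts': 44, 'n_stage_bouts': 19, 'n_band_power_samples': 138,
 'harmonic_check': {'theta_peak_hz': 7.0, 'gamma_peak_hz': 33.5,
                    'ratio': 4.79, 'harmonic_suspect': False}}
```

407 suprathreshold spike runs were screened and 5 accepted as SWDs (the
review table `swd_review.csv` lists all of them with their feature
scores); ~3581 s of the hour remain usable after masking. The harmonic
check finds the gamma peak at 33.5 Hz, not an integer multiple of the
7 Hz theta peak — evidence the measured gamma is not a theta harmonic.
The tidy outputs land in `demo_out/`:

```
demo_out/pac.csv  (mi = modulation index; z vs circular-shift surrogates)
phase_band   amp_band      mi        z  significant
     theta slow_gamma  0.0055   5720.8         True
     theta      delta  0.0000      3.2         True

demo_out/band_powers.csv, mean power (µV²) per state and band
state   delta  slow_gamma  theta
NREM    687.3       132.4   32.0
REM      31.0       131.6  417.0
walk     33.8       134.7  280.6
```

Theta-gamma coupling is detected (MI 0.0055) while theta-delta MI is three
orders of magnitude smaller; NREM is delta-dominant and REM/walking are
theta-dominant, as staged. `stage_rates.csv` reports per-stage seizure
counts, stage hours, and events/hour.

## Command line

`cagewave` exposes subcommands `simulate`, `swd-detect`, `swd-fit`,
`spectra`, `pac`, `behavior`, `sleep`, `summarize`, and `run` (full
pipeline); all take `--seed` where randomness is involved and write
CSV/JSON with a manifest.

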