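"""Synthetic paired EEG + pose home-cage sessions with ground truth.

The generator emulates the statistical structure the analyses assume, not
biophysics: state-dependent narrowband oscillations (delta 2-5 Hz, theta
6-10 Hz, slow gamma 25-45 Hz) over 1/f pink noise, theta-phase modulation
of gamma amplitude with depth kappa, spike-wave discharges as trains of
sharp biphasic templates at a 5-10 Hz spike rate with stage-dependent
Poisson rates, and pose tracks whose kinematic signatures separate sleep,
awake rest, walking, grooming and digging. Band frequencies are jittered
per bout so band-power estimation does not reduce to reading a single
spectral line.

Everything is deterministic given the seed, and the emitted ground truth
(state/stage bouts, SWD intervals and spike times, band amplitudes, kappa)
is consistent with the signals by construction.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (Interval, IntervalList, PoseTrack, Recording, write_eeg,
                 write_intervals, write_pose_table)

WAKE_STATES = ("rest", "walk", "groom", "dig")

#: Slow-gamma amplitude scaling across genotypes (gene-dosage pattern:
#: power increases as copy number falls, amplitude ratios 1 : 1.5 : 2.25).
GENOTYPE_GAMMA_SCALE = {"WT": 1.0, "HET": 1.5, "KO": 2.25}

_DEFAULT_BAND_AMPS = {
    # state: (A_delta, A_theta, A_gamma) in uV
    "NREM": (40.0, 6.0, 10.0),
    "REM": (4.0, 30.0, 10.0),
    "rest": (15.0, 10.0, 10.0),
    "walk": (6.0, 25.0, 10.0),
    "groom": (8.0, 15.0, 10.0),
    "dig": (8.0, 15.0, 10.0),
}

_DEFAULT_TRANSITIONS = {
    "sleep": {"rest": 1.0},
    "rest": {"sleep": 0.3, "walk": 0.4, "groom": 0.15, "dig": 0.15},
    "walk": {"rest": 0.6, "groom": 0.2, "dig": 0.2},
    "groom": {"rest": 0.5, "walk": 0.3, "dig": 0.2},
    "dig": {"rest": 0.5, "walk": 0.3, "groom": 0.2},
}


@dataclass
class SimConfig:
    """Parameters of one synthetic session; defaults are the study conditions."""

    fs: float = 200.0
    fps: float = 30.0
    session_s: float = 600.0
    animal_id: str = "sim0"
    genotype: str = "WT"

    # semi-Markov behavior scaffold
    states: tuple[str, ...] = ("sleep", "rest", "walk", "groom", "dig")
    dwell_mean_s: dict = field(default_factory=lambda: {
        "sleep": 400.0, "rest": 60.0, "walk": 30.0, "groom": 40.0, "dig": 40.0})
    dwell_min_s: dict = field(default_factory=lambda: {
        "sleep": 90.0, "rest": 15.0, "walk": 8.0, "groom": 8.0, "dig": 8.0})
    nrem_mean_s: float = 200.0
    nrem_min_s: float = 60.0
    rem_mean_s: float = 90.0
    rem_min_s: float = 30.0

    # EEG composition
    band_amps: dict = field(default_factory=lambda: {k: tuple(v) for k, v in
                                                     _DEFAULT_BAND_AMPS.items()})
    gamma_scale: float = 1.0
    kappa: float = 0.0                  # theta-phase modulation depth of gamma
    pink_scale: float = 15.0            # uV (std of the 1/f background)
    pink_exponent: float = 1.0

    # SWD events
    swd_rate_per_hour: dict = field(default_factory=dict)  # stage/state -> events/h
    swd_spike_rate_hz: float = 7.0      # must lie in [5, 10]
    swd_amp_mult: float = 3.0           # spike amplitude as multiple of baseline
    swd_dur_min_s: float = 1.0
    swd_dur_max_s: float = 4.0

    # pose geometry
    cage_cm: float = 30.0
    px_per_cm: float = 10.0
    dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.kappa < 1):
            raise ValueError("kappa must lie in [0, 1)")
        if not (5.0 <= self.swd_spike_rate_hz <= 10.0):
            raise ValueError("SWD spike rate must lie in [5, 10] Hz")
        if self.swd_amp_mult <= 0 or self.pink_scale < 0:
            raise ValueError("amplitudes and rates must be non-negative")

    def rate_for(self, label: str) -> float:
        return float(self.swd_rate_per_hour.get(label, 0.0))


@dataclass
class GroundTruth:
    behavior: IntervalList
    stages: IntervalList            # REM/NREM inside sleep bouts
    swd_events: IntervalList
    spike_times: list[np.ndarray]
    band_amps: dict
    kappa: float
    seed: int

    def effective_labels(self) -> IntervalList:
        """Behavior bouts with sleep replaced by its REM/NREM stages."""
        ivs = [iv for iv in self.behavior if iv.label != "sleep"]
        ivs.extend(self.stages)
        return IntervalList(ivs, validate=False)


def genotype_config(genotype: str, **overrides) -> SimConfig:
    """Preset per genotype: gamma dosage scaling and stage-dependent SWD rates.

    WT carries no SWDs ("no confirmed SWDs"); deletion carriers seize
    preferentially during REM (1.2/h) over NREM (0.1/h), with a low waking
    rate.
    """
    scale = GENOTYPE_GAMMA_SCALE[genotype]
    rates = {} if genotype == "WT" else {
        "REM": 1.2, "NREM": 0.1, "rest": 0.4, "walk": 0.2,
        "groom": 0.2, "dig": 0.2}
    return SimConfig(genotype=genotype, gamma_scale=scale,
                     swd_rate_per_hour=rates, **overrides)


# ---------------------------------------------------------------------------
# State scaffold
# ---------------------------------------------------------------------------

def _truncated_exp(rng, mean: float, lo: float) -> float:
    return lo + rng.exponential(max(mean - lo, 1e-6))


def sample_states(cfg: SimConfig, seed: int) -> tuple[IntervalList, IntervalList]:
    """Semi-Markov behavior bouts covering the session, plus sleep stages.

    Returns (behavior bouts, REM/NREM stage bouts); stages exactly tile
    every sleep bout, starting with NREM.
    """
    rng = np.random.default_rng(seed)
    states = list(cfg.states)
    bouts: list[Interval] = []
    stages: list[Interval] = []
    t = 0.0
    state = states[0]
    while t < cfg.session_s:
        dwell = _truncated_exp(rng, cfg.dwell_mean_s.get(state, 60.0),
                               cfg.dwell_min_s.get(state, 5.0))
        t1 = min(t + dwell, cfg.session_s)
        bouts.append(Interval(t, t1, state))
        if state == "sleep":
            stages.extend(_subdivide_sleep(rng, t, t1, cfg))
        t = t1
        if len(states) == 1:
            if t < cfg.session_s:
                continue
            break
        trans = {k: v for k, v in _DEFAULT_TRANSITIONS.get(state, {}).items()
                 if k in states}
        if not trans:
            trans = {s: 1.0 for s in states if s != state}
        names, probs = zip(*trans.items())
        probs = np.asarray(probs) / sum(probs)
        state = names[rng.choice(len(names), p=probs)]
    return IntervalList(bouts, validate=False), IntervalList(stages, validate=False)


def _subdivide_sleep(rng, t0: float, t1: float, cfg: SimConfig) -> list[Interval]:
    out: list[Interval] = []
    t, stage = t0, "NREM"
    while t < t1:
        mean, lo = ((cfg.nrem_mean_s, cfg.nrem_min_s) if stage == "NREM"
                    else (cfg.rem_mean_s, cfg.rem_min_s))
        dwell = _truncated_exp(rng, mean, lo)
        end = min(t + dwell, t1)
        if t1 - end < cfg.rem_min_s:   # absorb un-stageable remainder
            end = t1
        out.append(Interval(t, end, stage))
        t = end
        stage = "REM" if stage == "NREM" else "NREM"
    return out


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def pink_noise(n: int, fs: float, scale: float, exponent: float, rng) -> np.ndarray:
    """1/f^exponent Gaussian noise with standard deviation ``scale``."""
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white) * shaping, n=n)
    sd = x.std()
    return x * (scale / sd) if sd > 0 else x


_BAND_FREQS = {"delta": (2.0, 5.0), "theta": (6.0, 10.0), "gamma": (25.0, 45.0)}

#: phase-diffusion rate of the band oscillators (rad/sqrt(s)). Real EEG
#: rhythms are not phase-locked clocks; the random-walk phase gives each
#: band a finite spectral linewidth and makes time-shift surrogates a
#: valid PAC null (a strictly periodic modulator would be shift-invariant).
_PHASE_DIFFUSION = 0.8


def _osc_phase(rng, f: float, tt: np.ndarray, fs: float) -> np.ndarray:
    n = len(tt)
    walk = np.cumsum(rng.standard_normal(n)) * _PHASE_DIFFUSION / np.sqrt(fs)
    return 2 * np.pi * f * tt + rng.uniform(0, 2 * np.pi) + walk


def _cos_ramp(n_samples: int, n_ramp: int) -> np.ndarray:
    env = np.ones(n_samples)
    n_ramp = min(n_ramp, n_samples // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def _swd_template(fs: float, half_width_s: float = 0.02) -> np.ndarray:
    """Unit-peak biphasic spike: one sharp sine cycle, 20 ms per lobe."""
    period = 2 * half_width_s
    t = np.arange(int(round(period * fs))) / fs
    return np.sin(2 * np.pi * t / period)


def synth_eeg(behavior: IntervalList, stages: IntervalList, cfg: SimConfig,
              seed: int) -> tuple[Recording, GroundTruth]:
    """Render the EEG for a bout sequence; returns Recording + GroundTruth.

    Per effective bout (wake behavior or sleep stage) the three band
    oscillators get jittered frequencies and fresh phases; gamma amplitude
    is modulated by theta phase with depth kappa; 0.25 s cosine ramps
    smooth state boundaries. SWDs are Poisson per bout at the configured
    stage rate and replace the background with a spike train whose peak
    amplitude is ``swd_amp_mult`` times the background's average baseline
    voltage.
    """
    rng = np.random.default_rng(seed)
    n = int(round(cfg.session_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    x = pink_noise(n, cfg.fs, cfg.pink_scale, cfg.pink_exponent, rng)

    effective = [iv for iv in behavior if iv.label != "sleep"] + list(stages)
    effective.sort(key=lambda iv: iv.t0)
    ramp_n = int(round(0.25 * cfg.fs))
    for iv in effective:
        i0, i1 = int(round(iv.t0 * cfg.fs)), min(int(round(iv.t1 * cfg.fs)), n)
        if i1 <= i0:
            continue
        a_delta, a_theta, a_gamma = cfg.band_amps[iv.label]
        a_gamma = a_gamma * cfg.gamma_scale
        tt = t[i0:i1]
        env = _cos_ramp(i1 - i0, ramp_n)
        comp = np.zeros(i1 - i0)
        f_th = rng.uniform(*_BAND_FREQS["theta"])
        theta_phase = _osc_phase(rng, f_th, tt, cfg.fs)
        if a_delta > 0:
            f_d = rng.uniform(*_BAND_FREQS["delta"])
            comp += a_delta * np.sin(_osc_phase(rng, f_d, tt, cfg.fs))
        comp += a_theta * np.sin(theta_phase)
        if a_gamma > 0:
            f_g = rng.uniform(*_BAND_FREQS["gamma"])
            mod = (1 + cfg.kappa * np.cos(theta_phase)) / (1 + cfg.kappa)
            comp += a_gamma * mod * np.sin(_osc_phase(rng, f_g, tt, cfg.fs))
        x[i0:i1] += env * comp

    baseline = float(np.mean(np.abs(x - np.mean(x))))

    # SWD insertion
    events: list[Interval] = []
    spikes_per_event: list[np.ndarray] = []
    template = _swd_template(cfg.fs) * cfg.swd_amp_mult * baseline
    peak_offset = len(template) // 4  # template peak sits a quarter-cycle in
    for iv in effective:
        lam = cfg.rate_for(iv.label)
        if lam <= 0:
            continue
        n_ev = rng.poisson(lam * iv.duration / 3600.0)
        for _ in range(n_ev):
            dur = rng.uniform(cfg.swd_dur_min_s, cfg.swd_dur_max_s)
            if iv.duration < dur + 1.0:
                continue
            t0 = rng.uniform(iv.t0 + 0.5, iv.t1 - dur - 0.5)
            cand = Interval(t0, t0 + dur, "SWD")
            if any(c.t0 < cand.t1 + 1.0 and cand.t0 < c.t1 + 1.0 for c in events):
                continue
            spike_t = np.arange(t0 + 0.1, t0 + dur - 0.1, 1.0 / cfg.swd_spike_rate_hz)
            if spike_t.size < 4:
                continue
            i0, i1 = int(round(t0 * cfg.fs)), int(round((t0 + dur) * cfg.fs))
            seg = np.zeros(i1 - i0)
            for st in spike_t:
                j = int(round(st * cfg.fs)) - i0 - peak_offset
                j0, j1 = max(j, 0), min(j + len(template), len(seg))
                seg[j0:j1] += template[j0 - j:j1 - j]
            fade = _cos_ramp(i1 - i0, int(round(0.1 * cfg.fs)))
            x[i0:i1] = fade * seg + (1 - fade) * x[i0:i1]
            events.append(cand)
            spikes_per_event.append(spike_t)

    order = np.argsort([e.t0 for e in events])
    events = [events[k] for k in order]
    spikes_per_event = [spikes_per_event[k] for k in order]
    rec = Recording(samples=x, fs=cfg.fs, animal_id=cfg.animal_id,
                    genotype=cfg.genotype)
    truth = GroundTruth(behavior=behavior, stages=stages,
                        swd_events=IntervalList(events, validate=False),
                        spike_times=spikes_per_event,
                        band_amps=dict(cfg.band_amps), kappa=cfg.kappa, seed=seed)
    return rec, truth


# ---------------------------------------------------------------------------
# Pose synthesis
# ---------------------------------------------------------------------------

#: keypoint offsets in the animal frame (cm): +x is the heading direction,
#: +y is the animal's right; image y grows downward.
_LAYOUT = {
    "snout": (2.5, 0.0),
    "ear_left": (1.6, -1.0),
    "ear_right": (1.6, 1.0),
    "body_center": (0.0, 0.0),
    "tailbase": (-3.0, 0.0),
}


def _reflect(pos: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    folded = np.mod(pos - lo, 2 * span)
    return lo + np.where(folded > span, 2 * span - folded, folded)


def _smooth_noise(rng, n: int, fps: float, sigma: float, tau_s: float = 0.3
                  ) -> np.ndarray:
    w = rng.standard_normal(n)
    k = max(int(round(tau_s * fps)), 1)
    sm = np.convolve(w, np.ones(k) / k, mode="same")
    sd = sm.std()
    return sm * (sigma / sd) if sd > 0 else sm


def synth_pose(behavior: IntervalList, cfg: SimConfig, seed: int) -> PoseTrack:
    """Pose track realizing each state's kinematic signature.

    sleep: static, sub-0.5 cm/s breathing jitter; rest: slow drift with
    posture (dispersion) fluctuation; walk: correlated random walk at
    2-8 cm/s reflected at the walls; groom: static centroid, 4 Hz
    head-relative oscillation with the snout forward/up; dig: static
    centroid, 4 Hz vertical snout oscillation below the body-center axis.
    """
    rng = np.random.default_rng(seed)
    fps, L = cfg.fps, cfg.cage_cm
    n = int(round(cfg.session_s * fps))
    tt = np.arange(n) / fps
    cen = np.zeros((n, 2))
    heading = np.zeros(n)
    scale_osc = np.ones(n)
    head_dxy = np.zeros((n, 2))   # extra head-keypoint motion, animal frame
    pos = np.array([L / 2, L / 2])
    ang = 0.0
    for iv in behavior:
        i0, i1 = int(round(iv.t0 * fps)), min(int(round(iv.t1 * fps)), n)
        m = i1 - i0
        if m <= 0:
            continue
        tloc = tt[i0:i1] - tt[i0]
        if iv.label == "walk":
            speed = rng.uniform(2.5, 8.0)
            ang_series = ang + np.cumsum(rng.standard_normal(m)) * 0.8 / np.sqrt(fps)
            vel = speed / fps * np.column_stack([np.cos(ang_series),
                                                 np.sin(ang_series)])
            path = pos + np.cumsum(vel, axis=0)
            cen[i0:i1] = np.column_stack([_reflect(path[:, 0], 2, L - 2),
                                          _reflect(path[:, 1], 2, L - 2)])
            heading[i0:i1] = ang_series
            pos, ang = cen[i1 - 1].copy(), ang_series[-1]
        elif iv.label == "rest":
            drift_ang = ang + np.cumsum(rng.standard_normal(m)) * 0.4 / np.sqrt(fps)
            vel = 0.3 / fps * np.column_stack([np.cos(drift_ang), np.sin(drift_ang)])
            path = pos + np.cumsum(vel, axis=0)
            cen[i0:i1] = np.column_stack([_reflect(path[:, 0], 2, L - 2),
                                          _reflect(path[:, 1], 2, L - 2)])
            heading[i0:i1] = ang
            scale_osc[i0:i1] = 1 + 0.12 * np.sin(2 * np.pi * 0.5 * tloc
                                                 + rng.uniform(0, 2 * np.pi))
            pos = cen[i1 - 1].copy()
        elif iv.label == "sleep":
            breathe = 0.05 * np.sin(2 * np.pi * 1.0 * tloc)
            cen[i0:i1] = pos + np.column_stack([breathe, np.zeros(m)])
            heading[i0:i1] = ang
        elif iv.label in ("groom", "dig"):
            cen[i0:i1] = pos
            # groom: snout forward/up (image -y); dig: snout down (+y)
            ang = -np.pi / 2 if iv.label == "groom" else np.pi / 2
            heading[i0:i1] = ang
            # head bobbing along the snout axis: with heading -pi/2 (groom)
            # the snout oscillates vertically above the body axis, with
            # +pi/2 (dig) vertically below it
            head_dxy[i0:i1, 0] = 0.4 * np.sin(2 * np.pi * 4.0 * tloc)
        else:
            cen[i0:i1] = pos
            heading[i0:i1] = ang

    cos_h, sin_h = np.cos(heading), np.sin(heading)
    frames = {}
    head_set = {"snout", "ear_left", "ear_right"}
    for bp, (ox, oy) in _LAYOUT.items():
        dx = ox * scale_osc + (head_dxy[:, 0] if bp in head_set else 0.0)
        dy = oy * scale_osc + (head_dxy[:, 1] if bp in head_set else 0.0)
        gx = cen[:, 0] + dx * cos_h - dy * sin_h
        gy = cen[:, 1] + dx * sin_h + dy * cos_h
        gx = gx + _smooth_noise(rng, n, fps, 0.03)
        gy = gy + _smooth_noise(rng, n, fps, 0.03)
        lik = np.ones(n)
        if cfg.dropout_prob > 0:
            drop = rng.random(n) < cfg.dropout_prob
            gx[drop] += rng.normal(0, 2.0, drop.sum())
            gy[drop] += rng.normal(0, 2.0, drop.sum())
            lik[drop] = 0.3
        frames[(bp, "x")] = gx * cfg.px_per_cm
        frames[(bp, "y")] = gy * cfg.px_per_cm
        frames[(bp, "likelihood")] = lik
    data = pd.DataFrame(frames)
    data.columns = pd.MultiIndex.from_tuples(data.columns)
    return PoseTrack(frame_times=tt, data=data, px_per_cm=cfg.px_per_cm)


# ---------------------------------------------------------------------------
# Session-level convenience and dataset export
# ---------------------------------------------------------------------------

def simulate_session(cfg: SimConfig, seed: int
                     ) -> tuple[Recording, PoseTrack, GroundTruth]:
    """One paired EEG + pose session; sub-seeds are derived deterministically."""
    behavior, stages = sample_states(cfg, seed)
    rec, truth = synth_eeg(behavior, stages, cfg, seed + 1)
    pose = synth_pose(behavior, cfg, seed + 2)
    return rec, pose, truth


def generate_dataset(cfg: SimConfig, out_dir: str | Path, seed: int) -> dict:
    """Write a full session to disk; same seed -> byte-identical CSV truth.

    Files: session.edf, pose.csv, truth_states.csv, truth_stages.csv,
    truth_swd.csv, config.json, manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec, pose, truth = simulate_session(cfg, seed)
    write_eeg(rec, out / "session.edf")
    write_pose_table(pose, out / "pose.csv")
    write_intervals(truth.behavior, out / "truth_states.csv")
    write_intervals(truth.stages, out / "truth_stages.csv")
    swd = truth.swd_events.to_frame()
    swd["spike_times"] = [";".join(f"{v:.4f}" for v in st)
                          for st in truth.spike_times]
    swd.to_csv(out / "truth_swd.csv", index=False)
    cfg_dict = asdict(cfg)
    (out / "config.json").write_text(json.dumps(cfg_dict, indent=2, sort_keys=True))
    manifest = {
        "package": "cagewave",
        "seed": seed,
        "px_per_cm": cfg.px_per_cm,
        "files": {p.name: hashlib.md5(p.read_bytes()).hexdigest()
                  for p in sorted(out.glob("*")) if p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
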