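"""Spike-wave discharge (SWD) detection and masking.

SWDs — the EEG signature of absence seizures — are found by a supervised
procedure: (1) detect consecutive spikes exceeding 2.5x the average baseline
voltage of the whole recording, (2) group them into candidate events, (3)
score each candidate on three bounded features — spiking frequency (target
range 5-10 Hz), the 16-32 Hz harmonic fraction typical of SWD spectra, and
spike sharpness from the finest-scale Daubechies-4 wavelet detail — combined
through a logistic model whose weights can be calibrated against hand-scored
labels. Accepted events are then masked out of the recording before any
spectral analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .io import Interval, IntervalList, Recording

FEATURE_NAMES = ("f_freq", "f_harm", "f_sharp")

# Classic 4-tap Daubechies filter; PyWavelets names it by vanishing moments.
_D4_WAVELET = "db2"


@dataclass
class SWDCandidate:
    """A tentative SWD: interval, member spike times, features, score."""

    t0: float
    t1: float
    spike_times: np.ndarray
    features: dict[str, float] = field(default_factory=dict)
    score: float | None = None

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


def compute_baseline(rec: Recording) -> float:
    """Average baseline voltage: mean |x - mean(x)| over the whole recording."""
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    x = rec.samples
    return float(np.mean(np.abs(x - np.mean(x))))


def detect_spikes(rec: Recording, baseline_mult: float = 2.5,
                  refractory_s: float = 0.05,
                  baseline: float | None = None) -> np.ndarray:
    """Times (s) of local extrema with |amplitude| >= baseline_mult * baseline.

    Both polarities count (electrode polarity is arbitrary); detections are
    separated by at least ``refractory_s``.
    """
    if baseline is None:
        baseline = compute_baseline(rec)
    if baseline == 0:
        return np.array([])
    x = np.abs(rec.samples - np.mean(rec.samples))
    distance = max(int(round(refractory_s * rec.fs)), 1)
    peaks, _ = sps.find_peaks(x, height=baseline_mult * baseline, distance=distance)
    return rec.start_time + peaks / rec.fs


def _trim_run(run: np.ndarray, trim_factor: float = 1.6) -> np.ndarray:
    """Drop edge spikes whose gap to the run exceeds the core rhythm."""
    while len(run) >= 3:
        med = np.median(np.diff(run))
        if run[1] - run[0] > trim_factor * med:
            run = run[1:]
        elif run[-1] - run[-2] > trim_factor * med:
            run = run[:-1]
        else:
            break
    return run


def _regular_core(run: np.ndarray, min_spikes: int,
                  max_isi_ratio: float = 1.5) -> np.ndarray:
    """Longest rhythmically regular stretch of a spike run.

    SWD spiking is near-periodic while suprathreshold background peaks that
    weld onto a discharge are not, so the candidate is refined to the
    longest consecutive stretch whose inter-spike intervals stay within a
    ``max_isi_ratio`` max/min band. Falls back to edge trimming when no
    stretch reaches ``min_spikes``.
    """
    isi = np.diff(run)
    if isi.size < 2:
        return run
    best_lo, best_hi = 0, 0  # inclusive ISI index range of best stretch
    lo = 0
    for hi in range(len(isi)):
        while lo <= hi and (np.max(isi[lo:hi + 1]) >
                            max_isi_ratio * np.min(isi[lo:hi + 1])):
            lo += 1
        if hi - lo > best_hi - best_lo:
            best_lo, best_hi = lo, hi
    core = run[best_lo:best_hi + 2]
    if len(core) >= min_spikes:
        return core
    return _trim_run(run)


def assemble_candidates(spike_times: np.ndarray, max_gap_s: float = 0.3,
                        min_spikes: int = 4,
                        min_duration_s: float = 0.6) -> list[SWDCandidate]:
    """Group spikes into candidate events.

    Maximal runs with consecutive inter-spike gaps <= ``max_gap_s`` become
    candidates when they hold at least ``min_spikes`` spikes spanning at
    least ``min_duration_s``; arrhythmic edge spikes are trimmed first.
    The event interval extends one mean inter-spike interval beyond the
    first and last spike.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(spike_times) > max_gap_s)
    runs = np.split(spike_times, breaks + 1)
    out: list[SWDCandidate] = []
    for run in runs:
        if len(run) < min_spikes:
            continue
        run = _regular_core(run, min_spikes)
        if len(run) < min_spikes:
            continue
        span = run[-1] - run[0]
        if span < min_duration_s:
            continue
        mean_isi = span / (len(run) - 1)
        out.append(SWDCandidate(t0=run[0] - mean_isi, t1=run[-1] + mean_isi,
                                spike_times=run))
    return out


def feature_spike_frequency(cand: SWDCandidate, f_lo: float = 5.0,
                            f_hi: float = 10.0, ramp_hz: float = 2.0) -> float:
    """Score in [0,1]: 1 when the median spike rate lies in [f_lo, f_hi] Hz,
    falling linearly to 0 over ``ramp_hz`` outside the range."""
    if cand.n_spikes < 2:
        raise ValueError("spike-frequency feature needs >= 2 spikes")
    rate = float(np.median(1.0 / np.diff(cand.spike_times)))
    if rate < f_lo:
        excess = f_lo - rate
    elif rate > f_hi:
        excess = rate - f_hi
    else:
        return 1.0
    return float(max(0.0, 1.0 - excess / ramp_hz))


def feature_harmonic(cand: SWDCandidate, rec: Recording,
                     harm_lo: float = 16.0, harm_hi: float = 32.0,
                     total_lo: float = 1.0, total_hi: float = 45.0) -> float:
    """Fraction of 1-45 Hz event power lying in the 16-32 Hz harmonic band."""
    seg = rec.slice(cand.t0, cand.t1)
    if seg.size < 8:
        return 0.0
    freqs, psd = sps.periodogram(seg, fs=rec.fs, window="hann", detrend="constant")
    num = np.trapezoid(psd[(freqs >= harm_lo) & (freqs <= harm_hi)],
                       freqs[(freqs >= harm_lo) & (freqs <= harm_hi)])
    den = np.trapezoid(psd[(freqs >= total_lo) & (freqs <= total_hi)],
                       freqs[(freqs >= total_lo) & (freqs <= total_hi)])
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 1.0))


def _detail_concentration(x: np.ndarray, peak_idx: np.ndarray, fs: float,
                          half_win_s: float) -> tuple[float, float]:
    """(fraction of level-1 D4 detail energy within +-half_win_s of peaks,
    duty cycle of those windows). Detail coefficient k sits near sample 2k."""
    _, detail = pywt.dwt(x, _D4_WAVELET)
    energy = detail ** 2
    total = float(energy.sum())
    if total == 0 or len(x) == 0:
        return 0.0, 0.0
    half = max(int(round(half_win_s * fs / 2)), 1)  # in detail-coefficient units
    mask = np.zeros(len(detail), dtype=bool)
    for p in np.asarray(peak_idx, dtype=int) // 2:
        mask[max(p - half, 0):p + half + 1] = True
    return float(energy[mask].sum() / total), float(mask.mean())


def feature_sharpness(cand: SWDCandidate, rec: Recording,
                      half_win_s: float = 0.025) -> float:
    """Spike sharpness from the finest Daubechies-4 wavelet detail band.

    Measures how strongly level-1 detail energy of the event segment
    concentrates within +-25 ms of the detected spike peaks, rescaled
    against the duty cycle of those windows so that featureless background
    maps to ~0 and perfectly spike-concentrated detail energy maps to 1.
    The statistic is an energy ratio and thus gain-invariant.
    """
    seg = rec.slice(cand.t0, cand.t1)
    if seg.size < 8:
        return 0.0
    i0 = max(rec.time_to_sample(cand.t0), 0)
    peak_idx = np.round((cand.spike_times - rec.start_time) * rec.fs).astype(int) - i0
    peak_idx = peak_idx[(peak_idx >= 0) & (peak_idx < seg.size)]
    conc, duty = _detail_concentration(seg - np.mean(seg), peak_idx, rec.fs, half_win_s)
    if duty >= 1.0:
        return 1.0
    return float(np.clip((conc - duty) / (1.0 - duty), 0.0, 1.0))


def compute_features(cand: SWDCandidate, rec: Recording) -> dict[str, float]:
    feats = {
        "f_freq": feature_spike_frequency(cand),
        "f_harm": feature_harmonic(cand, rec),
        "f_sharp": feature_sharpness(cand, rec),
    }
    cand.features = feats
    return feats


def _logistic(z: float) -> float:
    return float(1.0 / (1.0 + np.exp(-z)))


class SWDDetector(BaseEstimator):
    """Logistic scorer over the three SWD features, sklearn-style.

    Parameters
    ----------
    baseline_mult : float
        Spike threshold as a multiple of the recording's average baseline
        voltage (mean |x - mean|); 2.5 by default.
    refractory_s, max_gap_s, min_spikes, min_duration_s
        Spike-detection refractory period and candidate-assembly rules.
    weights, bias
        Default logistic coefficients used before/without fitting.
    threshold
        Decision threshold on the logistic score.

    After :meth:`fit`, ``coef_``, ``intercept_`` and ``threshold_`` hold the
    calibrated model; :meth:`detect` uses them when present.
    """

    def __init__(self, baseline_mult: float = 2.5, refractory_s: float = 0.05,
                 max_gap_s: float = 0.3, min_spikes: int = 4,
                 min_duration_s: float = 0.6,
                 weights: tuple[float, float, float] = (2.0, 4.0, 4.0),
                 bias: float = -5.0, threshold: float = 0.5):
        self.baseline_mult = baseline_mult
        self.refractory_s = refractory_s
        self.max_gap_s = max_gap_s
        self.min_spikes = min_spikes
        self.min_duration_s = min_duration_s
        self.weights = weights
        self.bias = bias
        self.threshold = threshold

    # -- sklearn-facing API on feature matrices --------------------------

    def fit(self, X, y, seed: int = 0) -> "SWDDetector":
        """Calibrate weights/bias on labeled candidate features.

        ``X`` is (n, 3) in FEATURE_NAMES order (or a DataFrame with those
        columns); ``y`` is 1 for SWD, 0 for not-SWD. The decision threshold
        is set to maximize balanced accuracy on the training labels.
        """
        if isinstance(X, pd.DataFrame):
            X = X[list(FEATURE_NAMES)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("calibration needs both SWD and not-SWD labels")
        clf = LogisticRegression(C=10.0, random_state=seed)
        clf.fit(X, y)
        self.coef_ = clf.coef_[0].copy()
        self.intercept_ = float(clf.intercept_[0])
        scores = clf.predict_proba(X)[:, 1]
        self.threshold_ = _best_balanced_threshold(scores, y)
        return self

    def score_features(self, X) -> np.ndarray:
        """Logistic score in [0,1] for each feature row."""
        if isinstance(X, pd.DataFrame):
            X = X[list(FEATURE_NAMES)].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        w = getattr(self, "coef_", np.asarray(self.weights, dtype=float))
        b = getattr(self, "intercept_", self.bias)
        return 1.0 / (1.0 + np.exp(-(X @ w + b)))

    def predict(self, X) -> np.ndarray:
        thr = getattr(self, "threshold_", self.threshold)
        return (self.score_features(X) >= thr).astype(int)

    # -- recording-facing API ---------------------------------------------

    def detect(self, rec: Recording) -> tuple[IntervalList, pd.DataFrame]:
        """Full pipeline on a recording.

        Returns accepted events (score >= threshold) and a review table of
        every candidate with its features and score — the audit surface for
        manual verification of automated calls.
        """
        baseline = compute_baseline(rec)
        spikes = detect_spikes(rec, self.baseline_mult, self.refractory_s,
                               baseline=baseline)
        cands = assemble_candidates(spikes, self.max_gap_s, self.min_spikes,
                                    self.min_duration_s)
        rows, events = [], []
        thr = getattr(self, "threshold_", self.threshold)
        for cand in cands:
            feats = compute_features(cand, rec)
            cand.score = float(self.score_features([list(feats.values())])[0])
            accepted = cand.score >= thr
            rows.append({"t0": cand.t0, "t1": cand.t1, "n_spikes": cand.n_spikes,
                         **feats, "score": cand.score, "accepted": accepted})
            if accepted:
                events.append(Interval(cand.t0, cand.t1, "SWD", cand.score))
        review = pd.DataFrame(rows, columns=["t0", "t1", "n_spikes",
                                             *FEATURE_NAMES, "score", "accepted"])
        return IntervalList(events, validate=False), review

    # -- persistence -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        w = getattr(self, "coef_", np.asarray(self.weights, dtype=float))
        payload = {
            "weights": list(map(float, w)),
            "bias": float(getattr(self, "intercept_", self.bias)),
            "threshold": float(getattr(self, "threshold_", self.threshold)),
            "params": self.get_params(),
        }
        payload["params"]["weights"] = list(payload["params"]["weights"])
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SWDDetector":
        payload = json.loads(Path(path).read_text())
        params = payload.get("params", {})
        params["weights"] = tuple(params.get("weights", payload["weights"]))
        det = cls(**params)
        det.coef_ = np.asarray(payload["weights"], dtype=float)
        det.intercept_ = float(payload["bias"])
        det.threshold_ = float(payload["threshold"])
        return det


def _best_balanced_threshold(scores: np.ndarray, y: np.ndarray) -> float:
    """Threshold (midpoint grid over observed scores) maximizing balanced accuracy."""
    order = np.argsort(scores)
    ss = scores[order]
    cuts = np.concatenate([[0.0], (ss[1:] + ss[:-1]) / 2, [1.0]])
    best_thr, best_acc = 0.5, -1.0
    pos, neg = y == 1, y == 0
    for thr in cuts:
        pred = scores >= thr
        tpr = pred[pos].mean() if pos.any() else 0.0
        tnr = (~pred[neg]).mean() if neg.any() else 0.0
        acc = (tpr + tnr) / 2
        if acc > best_acc + 1e-12:
            best_acc, best_thr = acc, thr
    return float(best_thr)


def score_candidate(features: dict[str, float] | np.ndarray,
                    model: SWDDetector) -> float:
    """Logistic score of one feature vector under ``model``."""
    if isinstance(features, dict):
        features = [features[k] for k in FEATURE_NAMES]
    return float(model.score_features([list(features)])[0])


def fit_model(candidates: list[SWDCandidate], labels: pd.DataFrame,
              rec: Recording, seed: int = 0,
              overlap_tol_s: float = 0.5, **params) -> SWDDetector:
    """Fit a detector from candidates plus a hand-scored label table.

    A candidate is a positive when its onset falls within ``overlap_tol_s``
    of a labeled SWD interval (or overlaps one); otherwise negative.
    """
    X, y = [], []
    swd_rows = labels[labels["label"] == "SWD"]
    for cand in candidates:
        feats = cand.features or compute_features(cand, rec)
        X.append([feats[k] for k in FEATURE_NAMES])
        hit = ((swd_rows["t0"] - overlap_tol_s <= cand.t0)
               & (cand.t0 <= swd_rows["t1"] + overlap_tol_s)).any()
        y.append(int(hit))
    det = SWDDetector(**params)
    det.fit(np.asarray(X), np.asarray(y), seed=seed)
    return det


def detect_swd(rec: Recording, model: SWDDetector | None = None
               ) -> tuple[IntervalList, pd.DataFrame]:
    """Detect SWDs with ``model`` (default-parameter detector if None)."""
    return (model or SWDDetector()).detect(rec)


def remove_swd(rec: Recording, events: IntervalList, pad_s: float = 0.5,
               min_segment_s: float = 2.0) -> IntervalList:
    """Usable segments: the recording minus SWD events dilated by ``pad_s``.

    Segments shorter than ``min_segment_s`` (one spectral-analysis window)
    are dropped.
    """
    if pad_s < 0:
        raise ValueError("pad_s must be >= 0")
    t_start, t_end = rec.start_time, rec.start_time + rec.duration
    segs = events.merged(pad=pad_s).complement(t_start, t_end)
    keep = [iv for iv in segs if iv.duration >= min_segment_s]
    return IntervalList(keep, validate=False)
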