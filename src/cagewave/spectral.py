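"""SWD-masked power spectra, band power, bootstrap CIs, and phase-amplitude
coupling.

Spectra are Welch estimates over Hann windows confined to usable (SWD-free)
segments, normalized as densities so the integral over [0, fs/2] matches the
signal variance (Parseval). Phase-amplitude coupling uses the normalized
Kullback-Leibler modulation index with a circular-time-shift surrogate null.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import Band, Interval, IntervalList, Recording

log = logging.getLogger(__name__)


@dataclass
class Spectrum:
    freqs: np.ndarray
    psd: np.ndarray          # uV^2 / Hz, one-sided
    window_s: float
    overlap: float
    taper: str
    n_windows: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq": self.freqs, "psd": self.psd,
                             "n_windows": self.n_windows})


@dataclass
class PACResult:
    phase_band: Band
    amp_band: Band
    mi: float
    surrogate_mean: float
    surrogate_sd: float
    z: float
    p95: float
    significant: bool
    n_surrogates: int
    seed: int


def _whole_recording(rec: Recording) -> IntervalList:
    return IntervalList([Interval(rec.start_time, rec.start_time + rec.duration,
                                  "usable")], validate=False)


def compute_psd(rec: Recording, segments: IntervalList | None = None,
                window_s: float = 2.0, overlap: float = 0.5,
                taper: str = "hann") -> Spectrum:
    """Welch PSD over windows that lie wholly inside the given segments.

    No analysis window straddles an excluded (e.g. SWD) stretch. The
    estimate is a one-sided density whose integral over [0, fs/2] equals
    the segment-mean variance up to taper tolerance.
    """
    if segments is None:
        segments = _whole_recording(rec)
    nperseg = int(round(window_s * rec.fs))
    noverlap = int(round(nperseg * overlap))
    acc = None
    total_windows = 0
    freqs = None
    for iv in segments:
        seg = rec.slice(iv.t0, iv.t1)
        if seg.size < nperseg:
            continue
        n_win = 1 + (seg.size - nperseg) // (nperseg - noverlap)
        freqs, psd = sps.welch(seg, fs=rec.fs, window=taper, nperseg=nperseg,
                               noverlap=noverlap, detrend="constant")
        acc = psd * n_win if acc is None else acc + psd * n_win
        total_windows += n_win
    if acc is None:
        raise ValueError("no segment long enough for one analysis window "
                         f"({window_s} s)")
    return Spectrum(freqs=freqs, psd=acc / total_windows, window_s=window_s,
                    overlap=overlap, taper=taper, n_windows=total_windows)


def band_power(spec: Spectrum, band: Band) -> float:
    """Trapezoidal integral of the PSD over [f_lo, f_hi] (uV^2)."""
    f, p = spec.freqs, spec.psd
    if band.f_lo < f[0] or band.f_hi > f[-1]:
        raise ValueError(f"band {band.name} [{band.f_lo}, {band.f_hi}] outside "
                         f"frequency grid [{f[0]}, {f[-1]}]")
    grid = np.unique(np.concatenate([[band.f_lo], f[(f > band.f_lo) & (f < band.f_hi)],
                                     [band.f_hi]]))
    return float(np.trapezoid(np.interp(grid, f, p), grid))


def bout_band_powers(rec: Recording, bouts: IntervalList,
                     usable: IntervalList | None = None,
                     bands: tuple[Band, ...] = (), window_s: float = 2.0,
                     overlap: float = 0.5) -> pd.DataFrame:
    """One band-power sample per (bout, band), computed on the bout minus
    SWD exclusions. Bouts with no usable window are skipped and counted.

    ``usable`` is the usable-segment list from ``remove_swd``; None means
    the whole recording is usable.
    """
    if usable is None:
        usable = _whole_recording(rec)
    rows = []
    n_skipped = 0
    for bout_id, bout in enumerate(bouts):
        pieces = [Interval(max(iv.t0, bout.t0), min(iv.t1, bout.t1), "usable")
                  for iv in usable
                  if min(iv.t1, bout.t1) - max(iv.t0, bout.t0) >= window_s]
        if not pieces:
            n_skipped += 1
            continue
        try:
            spec = compute_psd(rec, IntervalList(pieces, validate=False),
                               window_s=window_s, overlap=overlap)
        except ValueError:
            n_skipped += 1
            continue
        for band in bands:
            rows.append({"bout_id": bout_id, "t0": bout.t0, "t1": bout.t1,
                         "state": bout.label, "animal_id": rec.animal_id,
                         "genotype": rec.genotype, "band": band.name,
                         "power": band_power(spec, band)})
    if n_skipped:
        log.info("bout_band_powers: skipped %d bouts with no usable window", n_skipped)
    df = pd.DataFrame(rows, columns=["bout_id", "t0", "t1", "state", "animal_id",
                                     "genotype", "band", "power"])
    df.attrs["n_skipped"] = n_skipped
    return df


def bootstrap_ci(values, n_boot: int = 1000, alpha: float = 0.05,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean; deterministic given ``seed``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("bootstrap CI needs at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def bandpass(x: np.ndarray, band: Band, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase 4th-order Butterworth bandpass (forward-backward)."""
    band.check_nyquist(fs)
    sos = sps.butter(order, [band.f_lo, band.f_hi], btype="bandpass",
                     fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def analytic_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase in (-pi, pi] of a band-limited signal."""
    return np.angle(sps.hilbert(x))


def analytic_amplitude(x: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude envelope (>= 0) of a band-limited signal."""
    return np.abs(sps.hilbert(x))


def modulation_index(phase: np.ndarray, amp: np.ndarray,
                     n_bins: int = 18) -> float:
    """Normalized KL modulation index in [0, 1].

    Mean amplitude is binned by phase, normalized to a distribution P, and
    compared with uniform: mi = KL(P || U) / log(n_bins). Empty phase bins
    are merged into their neighbor (dropped from the partition) with the
    normalization adjusted to the surviving bin count.
    """
    phase = np.asarray(phase, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if phase.shape != amp.shape:
        raise ValueError("phase and amplitude series must have equal length")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    which = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=amp, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    nonempty = counts > 0
    if not nonempty.all():
        log.warning("modulation_index: %d empty phase bins merged",
                    int((~nonempty).sum()))
    means = sums[nonempty] / counts[nonempty]
    n_eff = int(nonempty.sum())
    if n_eff < 2 or means.sum() <= 0:
        return 0.0
    p = means / means.sum()
    p = p[p > 0]
    # KL against uniform over the surviving n_eff bins
    kl = float(np.sum(p * np.log(p))) + np.log(n_eff)
    return float(max(kl / np.log(n_eff), 0.0))


def _masked_phase_amp(rec: Recording, segments: IntervalList, phase_band: Band,
                      amp_band: Band, edge_trim_s: float = 0.5
                      ) -> tuple[np.ndarray, np.ndarray]:
    phases, amps = [], []
    trim = int(round(edge_trim_s * rec.fs))
    for iv in segments:
        seg = rec.slice(iv.t0, iv.t1)
        if seg.size <= 2 * trim + int(rec.fs):
            continue
        ph = analytic_phase(bandpass(seg, phase_band, rec.fs))
        am = analytic_amplitude(bandpass(seg, amp_band, rec.fs))
        sl = slice(trim, seg.size - trim)
        phases.append(ph[sl])
        amps.append(am[sl])
    if not phases:
        return np.array([]), np.array([])
    return np.concatenate(phases), np.concatenate(amps)


def pac(rec: Recording, segments: IntervalList | None = None,
        phase_band: Band = Band("theta", 6, 10),
        amp_band: Band = Band("slow_gamma", 25, 45),
        n_bins: int = 18, n_surrogates: int = 200, seed: int = 0,
        min_total_s: float = 10.0) -> PACResult:
    """Phase-amplitude coupling with a circular-shift surrogate test.

    The observed modulation index is compared with ``n_surrogates``
    surrogates in which the amplitude series is circularly shifted by a
    uniform lag of at least 1 s, breaking the phase-amplitude relation while
    preserving both marginals. Coupling is significant when the observed mi
    exceeds the surrogate 95th percentile.
    """
    if segments is None:
        segments = _whole_recording(rec)
    if segments.total_duration() < min_total_s:
        raise ValueError(f"need >= {min_total_s} s of usable signal for PAC, "
                         f"got {segments.total_duration():.1f} s")
    phase, amp = _masked_phase_amp(rec, segments, phase_band, amp_band)
    if phase.size == 0:
        raise ValueError("no segment long enough for PAC after edge trimming")
    mi = modulation_index(phase, amp, n_bins)
    rng = np.random.default_rng(seed)
    min_shift = int(rec.fs)  # >= 1 s
    n = phase.size
    sur = np.empty(n_surrogates)
    for k in range(n_surrogates):
        shift = int(rng.integers(min_shift, n - min_shift)) if n > 2 * min_shift else n // 2
        sur[k] = modulation_index(phase, np.roll(amp, shift), n_bins)
    s_mean, s_sd = float(sur.mean()), float(sur.std(ddof=1))
    z = (mi - s_mean) / s_sd if s_sd > 0 else np.nan
    p95 = float(np.percentile(sur, 95))
    return PACResult(phase_band=phase_band, amp_band=amp_band, mi=float(mi),
                     surrogate_mean=s_mean, surrogate_sd=s_sd, z=float(z),
                     p95=p95, significant=bool(mi > p95),
                     n_surrogates=n_surrogates, seed=seed)


def harmonic_check(spec: Spectrum, theta: Band = Band("theta", 6, 10),
                   gamma: Band = Band("slow_gamma", 25, 45),
                   tol: float = 0.05) -> dict:
    """Diagnostic for the theta-harmonic concern.

    Finds the spectral peak in the theta and slow-gamma bands and flags
    ``harmonic_suspect`` when the gamma:theta peak-frequency ratio lies
    within ``tol`` of an integer — i.e. when measured gamma could be a mere
    harmonic of theta rather than an independent rhythm.
    """
    f, p = spec.freqs, spec.psd
    # require non-negligible prominence so numerical leakage floors and
    # noise ripples do not count as rhythm peaks
    peaks, _ = sps.find_peaks(p, prominence=1e-4 * float(np.max(p)))

    def band_peak(band: Band) -> float | None:
        sel = peaks[(f[peaks] >= band.f_lo) & (f[peaks] <= band.f_hi)]
        if sel.size == 0:
            return None
        return float(f[sel[np.argmax(p[sel])]])

    theta_peak = band_peak(theta)
    gamma_peak = band_peak(gamma)
    report: dict = {"theta_peak_hz": theta_peak, "gamma_peak_hz": gamma_peak,
                    "ratio": None, "harmonic_suspect": None}
    if theta_peak and gamma_peak:
        ratio = gamma_peak / theta_peak
        report["ratio"] = ratio
        report["harmonic_suspect"] = bool(abs(ratio - round(ratio)) <= tol)
    return report
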