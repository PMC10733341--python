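"""Data model and I/O for EEG recordings, pose tables, and interval lists.

All times are seconds on the EEG session clock; intervals are half-open
``[t0, t1)`` and map to sample indices via ``floor(t * fs)``, so abutting
bouts never double-count a sample.
"""
from __future__ import annotations

import io as _stdio
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "HET", "KO")

#: Canonical analysis bands. Delta and theta delimit the sleep-staging ratio;
#: slow gamma is the 25-45 Hz band whose power tracks gene dosage; the SWD
#: harmonic band holds the 16-32 Hz energy typical of spike-wave discharges.
DELTA = ("delta", 2.0, 5.0)
THETA = ("theta", 6.0, 10.0)
SLOW_GAMMA = ("slow_gamma", 25.0, 45.0)
SWD_HARMONIC = ("swd_harmonic", 16.0, 32.0)


class FormatError(ValueError):
    """Raised when a file cannot be parsed in the declared format."""


@dataclass(frozen=True)
class Band:
    """A named frequency band ``[f_lo, f_hi]`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})")

    def check_nyquist(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(f"band {self.name} upper edge {self.f_hi} Hz >= Nyquist {fs / 2} Hz")


BAND_DELTA = Band(*DELTA)
BAND_THETA = Band(*THETA)
BAND_SLOW_GAMMA = Band(*SLOW_GAMMA)
BAND_SWD_HARMONIC = Band(*SWD_HARMONIC)
DEFAULT_BANDS = (BAND_DELTA, BAND_THETA, BAND_SLOW_GAMMA)


@dataclass
class Recording:
    """A uniformly sampled single-channel EEG trace.

    Parameters
    ----------
    samples : ndarray
        Voltage samples in microvolts.
    fs : float
        Sampling rate in Hz.
    start_time : float
        Session-clock time of sample 0, seconds.
    animal_id : str
    genotype : str
        One of ``WT`` (wildtype), ``HET`` (heterozygous deletion),
        ``KO`` (homozygous deletion).
    """

    samples: np.ndarray
    fs: float
    start_time: float = 0.0
    animal_id: str = ""
    genotype: str = "WT"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def time_to_sample(self, t: float) -> int:
        """Session time (s) -> sample index, floor convention."""
        return int(np.floor((t - self.start_time) * self.fs))

    def slice(self, t0: float, t1: float) -> np.ndarray:
        """Samples of the half-open interval [t0, t1)."""
        i0 = max(self.time_to_sample(t0), 0)
        i1 = min(self.time_to_sample(t1), self.n_samples)
        return self.samples[i0:i1]


@dataclass(frozen=True)
class Interval:
    t0: float
    t1: float
    label: str = ""
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.t0 < self.t1:
            raise ValueError(f"need t0 < t1, got ({self.t0}, {self.t1})")

    @property
    def duration(self) -> float:
        return self.t1 - self.t0


class IntervalList:
    """An ordered list of half-open labeled intervals.

    Within one label class intervals must be non-overlapping once merged;
    the constructor sorts by onset and validates.
    """

    def __init__(self, intervals: Iterable[Interval] = (), validate: bool = True):
        ivs = sorted(intervals, key=lambda iv: (iv.t0, iv.t1))
        if validate:
            last_end: dict[str, float] = {}
            for iv in ivs:
                if iv.label in last_end and iv.t0 < last_end[iv.label]:
                    raise ValueError(f"overlapping intervals with label {iv.label!r} at t0={iv.t0}")
                last_end[iv.label] = iv.t1
        self.intervals: list[Interval] = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalList):
            return NotImplemented
        if len(self) != len(other):
            return False
        for a, b in zip(self.intervals, other.intervals):
            sa = -1.0 if a.score is None else a.score
            sb = -1.0 if b.score is None else b.score
            if not (np.isclose(a.t0, b.t0) and np.isclose(a.t1, b.t1)
                    and a.label == b.label and np.isclose(sa, sb)):
                return False
        return True

    def total_duration(self) -> float:
        return float(sum(iv.duration for iv in self.intervals))

    def labels(self) -> list[str]:
        return sorted({iv.label for iv in self.intervals})

    def with_label(self, label: str) -> "IntervalList":
        return IntervalList([iv for iv in self.intervals if iv.label == label], validate=False)

    def merged(self, pad: float = 0.0, label: str | None = None) -> "IntervalList":
        """Union of all intervals dilated by ``pad`` on each side.

        The result carries ``label`` (default: label of the first member of
        each merged run) and no scores. Idempotent and order-independent.
        """
        if not self.intervals:
            return IntervalList([])
        spans = sorted((iv.t0 - pad, iv.t1 + pad, iv.label) for iv in self.intervals)
        out: list[Interval] = []
        cur0, cur1, curlab = spans[0]
        for t0, t1, lab in spans[1:]:
            if t0 <= cur1:
                cur1 = max(cur1, t1)
            else:
                out.append(Interval(cur0, cur1, label if label is not None else curlab))
                cur0, cur1, curlab = t0, t1, lab
        out.append(Interval(cur0, cur1, label if label is not None else curlab))
        return IntervalList(out, validate=False)

    def complement(self, t_start: float, t_end: float, label: str = "usable") -> "IntervalList":
        """Gaps between merged intervals, clipped to [t_start, t_end)."""
        out: list[Interval] = []
        cursor = t_start
        for iv in self.merged():
            lo, hi = max(iv.t0, t_start), min(iv.t1, t_end)
            if hi <= cursor:
                continue
            if lo > cursor:
                out.append(Interval(cursor, lo, label))
            cursor = max(cursor, hi)
        if cursor < t_end:
            out.append(Interval(cursor, t_end, label))
        return IntervalList(out, validate=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t0": [iv.t0 for iv in self.intervals],
                "t1": [iv.t1 for iv in self.intervals],
                "label": [iv.label for iv in self.intervals],
                "score": [np.nan if iv.score is None else iv.score for iv in self.intervals],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntervalList":
        ivs = []
        for row in df.itertuples(index=False):
            score = getattr(row, "score", np.nan)
            score = None if score is None or (isinstance(score, float) and np.isnan(score)) else float(score)
            ivs.append(Interval(float(row.t0), float(row.t1), str(row.label), score))
        return cls(ivs)


@dataclass
class PoseTrack:
    """DeepLabCut-style pose track: per-frame keypoint (x, y, likelihood).

    ``data`` has a two-level column index (bodypart, coord) with coords
    x, y (pixels) and likelihood in [0, 1]; rows are frames.
    """

    frame_times: np.ndarray
    data: pd.DataFrame
    px_per_cm: float = 10.0

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.size != len(self.data):
            raise ValueError("frame_times length must match data rows")
        if self.frame_times.size > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        lik = self.likelihoods()
        if ((lik < 0) | (lik > 1)).any().any():
            raise ValueError("likelihood values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def fps(self) -> float:
        dt = np.median(np.diff(self.frame_times)) if self.n_frames > 1 else np.nan
        return 1.0 / dt

    @property
    def keypoints(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    def xy(self, keypoint: str) -> np.ndarray:
        """(n_frames, 2) pixel coordinates of one keypoint."""
        return self.data[keypoint][["x", "y"]].to_numpy(dtype=float)

    def likelihoods(self) -> pd.DataFrame:
        return self.data.xs("likelihood", axis=1, level=1)


@dataclass(frozen=True)
class TimelineAlignment:
    """Shared clock between an EEG recording and a pose track.

    ``offset_s`` is the EEG-session time of pose frame 0; the mapping is
    invertible by construction.
    """

    eeg: Recording
    pose: PoseTrack
    offset_s: float = 0.0

    def pose_time_to_eeg(self, t_pose: float) -> float:
        return t_pose + self.offset_s

    def eeg_time_to_pose(self, t_eeg: float) -> float:
        return t_eeg - self.offset_s

    def interval_to_samples(self, t0: float, t1: float) -> tuple[int, int]:
        """EEG-clock interval [t0, t1) -> half-open sample range."""
        eeg_end = self.eeg.start_time + self.eeg.duration
        if t0 < self.eeg.start_time or t1 > eeg_end + 1e-9:
            raise ValueError(f"interval ({t0}, {t1}) outside EEG span "
                             f"[{self.eeg.start_time}, {eeg_end})")
        return self.eeg.time_to_sample(t0), self.eeg.time_to_sample(t1)

    def interval_to_frames(self, t0: float, t1: float) -> tuple[int, int]:
        """EEG-clock interval -> half-open pose frame range."""
        tp0, tp1 = self.eeg_time_to_pose(t0), self.eeg_time_to_pose(t1)
        times = self.pose.frame_times
        if tp0 < times[0] - 1e-9 or tp1 > times[-1] + 1.0 / self.pose.fps + 1e-9:
            raise ValueError(f"interval ({t0}, {t1}) outside pose span")
        return int(np.searchsorted(times, tp0 - 1e-9)), int(np.searchsorted(times, tp1 - 1e-9))


# ---------------------------------------------------------------------------
# EDF writing (minimal single-channel EDF, 16-bit) and EEG reading
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_eeg(rec: Recording, path: str | Path) -> None:
    """Write a Recording as single-channel 16-bit EDF.

    Physical units are microvolts; the trace is quantized onto a symmetric
    physical range covering the data, so round-trip error is bounded by one
    16-bit quantization step. Signals not a whole number of seconds long are
    padded (with the final sample value) to fill the last 1-s data record.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    ns = int(round(fs))
    x = rec.samples
    n_rec = int(np.ceil(x.size / ns)) if x.size else 0
    pad = n_rec * ns - x.size
    if pad:
        x = np.concatenate([x, np.full(pad, x[-1] if x.size else 0.0)])
    phys_max = max(float(np.max(np.abs(x))) if x.size else 1.0, 1e-6)
    phys_max = float(np.ceil(phys_max * 1.01))
    dig_max, dig_min = 32767, -32768
    scale = dig_max / phys_max
    digital = np.clip(np.round(x * scale), dig_min, dig_max).astype("<i2")

    hdr = _stdio.BytesIO()
    hdr.write(_edf_field("0", 8))                       # version
    hdr.write(_edf_field(f"{rec.animal_id} {rec.genotype}".strip() or "X", 80))
    hdr.write(_edf_field("Startdate 01-JAN-2000", 80))  # recording id
    hdr.write(_edf_field("01.01.00", 8))                # start date
    hdr.write(_edf_field("00.00.00", 8))                # start time
    hdr.write(_edf_field(256 + 256, 8))                 # header bytes
    hdr.write(_edf_field("", 44))                       # reserved
    hdr.write(_edf_field(n_rec, 8))
    hdr.write(_edf_field("1", 8))                       # record duration s
    hdr.write(_edf_field("1", 4))                       # n signals
    # per-signal fields
    hdr.write(_edf_field("EEG", 16))
    hdr.write(_edf_field("", 80))                       # transducer
    hdr.write(_edf_field("uV", 8))
    hdr.write(_edf_field(f"{-phys_max:g}", 8))
    hdr.write(_edf_field(f"{phys_max:g}", 8))
    hdr.write(_edf_field(dig_min, 8))
    hdr.write(_edf_field(dig_max, 8))
    hdr.write(_edf_field("", 80))                       # prefiltering
    hdr.write(_edf_field(ns, 8))
    hdr.write(_edf_field("", 32))                       # reserved
    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        fh.write(digital.tobytes())


def read_eeg(path: str | Path, fs_hint: float | None = None, channel: str | None = None,
             **meta) -> Recording:
    """Read an EEG trace from EDF or one-column delimited text.

    EDF files are read with MNE (fs from the header; first channel unless
    ``channel`` names one). Text files are one sample per line in microvolts
    and require ``fs_hint``. Extra keyword arguments (``animal_id``,
    ``genotype``, ``start_time``) pass through to :class:`Recording`.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing file: {path}")
    head = path.open("rb").read(8)
    if head[:1] == b"0" and path.suffix.lower() == ".edf":
        import mne

        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as exc:  # pragma: no cover - mne error variety
            raise FormatError(f"unreadable EDF header in {path}: {exc}") from exc
        names = raw.ch_names
        pick = channel if channel is not None else names[0]
        if pick not in names:
            raise FormatError(f"channel {pick!r} not in {names}")
        data = raw.get_data(picks=[pick])[0] * 1e6  # V -> uV
        return Recording(samples=data, fs=float(raw.info["sfreq"]), **meta)
    if path.suffix.lower() == ".edf":
        raise FormatError(f"unreadable EDF header in {path}")
    if fs_hint is None:
        raise ValueError("fs_hint is required for delimited-text EEG")
    try:
        data = np.loadtxt(path, dtype=float, ndmin=1)
    except ValueError as exc:
        raise FormatError(f"cannot parse {path} as one-column text: {exc}") from exc
    if data.ndim != 1:
        raise FormatError("text EEG must be one column")
    return Recording(samples=data, fs=float(fs_hint), **meta)


# ---------------------------------------------------------------------------
# Pose tables (DLC-style three-row header)
# ---------------------------------------------------------------------------

def write_pose_table(track: PoseTrack, path: str | Path, scorer: str = "cagewave") -> None:
    df = track.data.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(scorer, bp, coord) for bp, coord in df.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    df.to_csv(path, index_label="frame")


def read_pose_table(path: str | Path, px_per_cm: float = 10.0,
                    fps: float = 30.0) -> PoseTrack:
    """Read a DLC-style pose CSV (scorer / bodyparts / coords header rows).

    Frame times come from the frame index divided by ``fps``. Every bodypart
    must carry x, y and likelihood columns.
    """
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as a DLC pose table: {exc}") from exc
    df.columns = pd.MultiIndex.from_tuples([(bp, coord) for _, bp, coord in df.columns])
    for bp in dict.fromkeys(df.columns.get_level_values(0)):
        cols = set(df[bp].columns)
        if not {"x", "y", "likelihood"} <= cols:
            raise FormatError(f"bodypart {bp!r} missing x/y/likelihood columns (has {cols})")
    frame_times = df.index.to_numpy(dtype=float) / fps
    return PoseTrack(frame_times=frame_times, data=df.astype(float), px_per_cm=px_per_cm)


# ---------------------------------------------------------------------------
# Interval and label tables
# ---------------------------------------------------------------------------

def write_intervals(events: IntervalList, path: str | Path) -> None:
    events.to_frame().to_csv(path, index=False)


def read_intervals(path: str | Path) -> IntervalList:
    df = pd.read_csv(path)
    missing = {"t0", "t1", "label"} - set(df.columns)
    if missing:
        raise FormatError(f"interval file {path} missing columns {sorted(missing)}")
    return IntervalList.from_frame(df)


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a hand-scored label table: columns t0, t1, label in {SWD, not-SWD}."""
    df = pd.read_csv(path)
    missing = {"t0", "t1", "label"} - set(df.columns)
    if missing:
        raise FormatError(f"label file {path} missing columns {sorted(missing)}")
    bad = set(df["label"]) - {"SWD", "not-SWD"}
    if bad:
        raise ValueError(f"labels must be SWD / not-SWD, got extra {sorted(bad)}")
    if (df["t1"] <= df["t0"]).any():
        raise ValueError("label table has intervals with t1 <= t0")
    return df
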