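"""Behavioral-state classification from pose, REM/NREM staging from EEG,
bout metrics, and per-stage seizure rates.

The behavior classifier assigns each usable video frame one of five
home-cage states — sleep, awake rest, walking, grooming, digging — from
kinematic features of a DeepLabCut-style pose track. Sleep is then staged
into REM and NREM from the EEG theta (6-10 Hz) to delta (2-5 Hz) power
ratio, computed on SWD-masked epochs. Without EMG, REM here is "EEG-only
REM": theta-dominant sleep, not atonia-confirmed REM.

The kinematic thresholds are operational definitions chosen for synthetic
testability; applying them to real videos requires recalibration.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator

from .io import Band, Interval, IntervalList, PoseTrack, Recording
from .spectral import band_power, bandpass, compute_psd

log = logging.getLogger(__name__)

BEHAVIOR_STATES = ("sleep", "rest", "walk", "groom", "dig")
SLEEP_STAGES = ("REM", "NREM")

HEAD_KEYPOINTS = ("snout", "ear_left", "ear_right")


# ---------------------------------------------------------------------------
# Pose preprocessing and kinematics
# ---------------------------------------------------------------------------

def pose_preprocess(track: PoseTrack, likelihood_min: float = 0.9,
                    smooth_s: float = 0.25, max_gap_s: float = 1.0
                    ) -> tuple[PoseTrack, IntervalList]:
    """Interpolate low-likelihood frames and median-smooth each keypoint.

    Frames with likelihood below ``likelihood_min`` are linearly
    interpolated per keypoint; coordinates are then median-filtered over
    ``smooth_s``. Dropout gaps longer than ``max_gap_s`` are returned as
    unusable intervals. Keypoints with > 50% low-likelihood frames trigger
    a quality warning.
    """
    fps = track.fps
    kernel = int(round(smooth_s * fps))
    kernel += 1 - kernel % 2  # odd
    data = track.data.copy()
    unusable: list[Interval] = []
    for bp in track.keypoints:
        lik = data[(bp, "likelihood")].to_numpy(dtype=float)
        bad = lik < likelihood_min
        if bad.mean() > 0.5:
            log.warning("keypoint %s: %.0f%% low-likelihood frames", bp,
                        100 * bad.mean())
        for coord in ("x", "y"):
            s = pd.Series(data[(bp, coord)].to_numpy(dtype=float))
            s[bad] = np.nan
            s = s.interpolate(limit_direction="both")
            data[(bp, coord)] = sps.medfilt(s.to_numpy(), kernel)
        # gaps longer than max_gap_s
        for run0, run1 in _bool_runs(bad):
            if (run1 - run0) / fps > max_gap_s:
                unusable.append(Interval(track.frame_times[run0],
                                         track.frame_times[min(run1, track.n_frames - 1)]
                                         + 1.0 / fps, "unusable"))
    cleaned = PoseTrack(frame_times=track.frame_times, data=data,
                        px_per_cm=track.px_per_cm)
    gaps = IntervalList(unusable, validate=False).merged() if unusable else IntervalList([])
    return cleaned, gaps


def _bool_runs(mask: np.ndarray):
    """Yield (start, stop) index pairs of True runs (stop exclusive)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    for chunk in np.split(idx, breaks + 1):
        yield int(chunk[0]), int(chunk[-1] + 1)


def _smooth(x: np.ndarray, fps: float, win_s: float) -> np.ndarray:
    from scipy.ndimage import uniform_filter1d

    n = max(int(round(win_s * fps)), 1)
    return uniform_filter1d(np.asarray(x, dtype=float), size=n, mode="nearest")


def centroid_xy(track: PoseTrack) -> np.ndarray:
    """(n_frames, 2) mean of all body keypoints, pixels."""
    return np.mean([track.xy(bp) for bp in track.keypoints], axis=0)


def centroid_speed(track: PoseTrack, smooth_s: float = 0.5) -> np.ndarray:
    """Centroid speed in cm/s.

    Positions are smoothed over ``smooth_s`` before the centered finite
    difference so that fast in-place oscillations (grooming, digging,
    tracking jitter) do not masquerade as locomotion; the speed magnitude
    is then lightly smoothed again.
    """
    fps = track.fps
    xy = centroid_xy(track) / track.px_per_cm
    xy = np.column_stack([_smooth(xy[:, 0], fps, smooth_s),
                          _smooth(xy[:, 1], fps, smooth_s)])
    vel = np.gradient(xy, 1.0 / fps, axis=0)
    speed = np.hypot(vel[:, 0], vel[:, 1])
    return _smooth(speed, fps, smooth_s)


def _band_speed(disp_cm: np.ndarray, fps: float, f_lo: float = 2.0,
                f_hi: float = 7.0, rms_win_s: float = 1.0) -> np.ndarray:
    """Rolling RMS speed (cm/s) of the 2-7 Hz component of a displacement."""
    filt = bandpass(disp_cm - np.mean(disp_cm), Band("osc", f_lo, f_hi), fps)
    vel = np.gradient(filt, 1.0 / fps)
    # clip: the moving average of a square can go epsilon-negative
    return np.sqrt(np.clip(_smooth(vel ** 2, fps, rms_win_s), 0.0, None))


# ---------------------------------------------------------------------------
# Behavior classification
# ---------------------------------------------------------------------------

class BehaviorClassifier(BaseEstimator):
    """Rule-based five-state home-cage behavior classifier.

    Frame-level rules (all thresholds config-exposed, speeds in cm/s):

    * sleep — immobility (centroid speed < ``sleep_speed_max`` and keypoint
      dispersion motion < ``sleep_disp_max``) sustained >= ``sleep_min_s``;
    * groom — slow centroid with head-relative 2-7 Hz oscillation speed
      >= ``osc_speed_min`` while the snout is not below the body axis,
      sustained >= ``groom_min_s``;
    * dig — slow centroid with snout vertical 2-7 Hz oscillation speed
      >= ``osc_speed_min`` while the snout is below the body-center axis,
      sustained >= ``dig_min_s``;
    * walk — centroid speed >= ``walk_speed_min`` sustained >= ``walk_min_s``;
    * rest — awake residual.

    Precedence: sleep > groom > dig > walk > rest. Bouts shorter than their
    per-state minimum are merged into the longer neighbor, so the output
    partitions the usable track.
    """

    def __init__(self, sleep_speed_max: float = 0.5, sleep_disp_max: float = 0.3,
                 sleep_min_s: float = 40.0, walk_speed_min: float = 2.0,
                 walk_min_s: float = 1.0, slow_speed_max: float = 1.0,
                 osc_speed_min: float = 1.5, groom_min_s: float = 3.0,
                 dig_min_s: float = 3.0, below_margin_cm: float = 0.2):
        self.sleep_speed_max = sleep_speed_max
        self.sleep_disp_max = sleep_disp_max
        self.sleep_min_s = sleep_min_s
        self.walk_speed_min = walk_speed_min
        self.walk_min_s = walk_min_s
        self.slow_speed_max = slow_speed_max
        self.osc_speed_min = osc_speed_min
        self.groom_min_s = groom_min_s
        self.dig_min_s = dig_min_s
        self.below_margin_cm = below_margin_cm

    def frame_labels(self, track: PoseTrack) -> np.ndarray:
        fps = track.fps
        n = track.n_frames
        speed = centroid_speed(track)
        cen = centroid_xy(track) / track.px_per_cm

        # dispersion motion: rate of change of mean keypoint-to-centroid
        # distance, rectified before smoothing. Averaging distances over
        # keypoints suppresses tracking jitter while posture changes
        # (stretching, head bobbing) survive.
        disp = np.mean([np.hypot(*(track.xy(bp) / track.px_per_cm - cen).T)
                        for bp in track.keypoints], axis=0)
        disp_motion = _smooth(np.abs(np.gradient(disp, 1.0 / fps)), fps, 0.5)

        kps = set(track.keypoints)
        have_head = "snout" in kps and "body_center" in kps
        if have_head:
            snout = track.xy("snout") / track.px_per_cm
            body = track.xy("body_center") / track.px_per_cm
            head_rel = snout - cen
            head_osc = np.maximum(_band_speed(head_rel[:, 0], fps),
                                  _band_speed(head_rel[:, 1], fps))
            snout_vert_osc = _band_speed(snout[:, 1], fps)
            snout_below = _smooth((snout[:, 1] - body[:, 1]).astype(float), fps, 0.5) \
                > self.below_margin_cm  # image y grows downward
        else:
            log.warning("groom/dig disabled: snout or body_center keypoint missing")
            head_osc = snout_vert_osc = np.zeros(n)
            snout_below = np.zeros(n, dtype=bool)

        immobile = (speed < self.sleep_speed_max) & (disp_motion < self.sleep_disp_max)
        sleep = _sustained(immobile, fps, self.sleep_min_s)
        slow = speed < self.slow_speed_max
        groom = slow & (head_osc >= self.osc_speed_min) & ~snout_below
        groom = _sustained(groom, fps, self.groom_min_s)
        dig = slow & (snout_vert_osc >= self.osc_speed_min) & snout_below
        dig = _sustained(dig, fps, self.dig_min_s)
        walk = _sustained(speed >= self.walk_speed_min, fps, self.walk_min_s)

        labels = np.full(n, "rest", dtype=object)
        labels[walk] = "walk"
        labels[dig] = "dig"
        labels[groom] = "groom"
        labels[sleep] = "sleep"
        return labels

    def predict_bouts(self, track: PoseTrack) -> IntervalList:
        """Classify and return an exhaustive, mutually exclusive bout list."""
        labels = self.frame_labels(track)
        fps = track.fps
        min_s = {"sleep": self.sleep_min_s, "walk": self.walk_min_s,
                 "groom": self.groom_min_s, "dig": self.dig_min_s, "rest": 0.0}
        labels = _merge_short_runs(labels, fps, min_s)
        times = track.frame_times
        dt = 1.0 / fps
        bouts = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                bouts.append(Interval(times[start], times[i - 1] + dt,
                                      str(labels[start])))
                start = i
        return IntervalList(bouts, validate=False)


def _sustained(mask: np.ndarray, fps: float, min_s: float) -> np.ndarray:
    """Keep only True runs lasting at least ``min_s`` seconds."""
    out = np.zeros_like(mask)
    need = int(round(min_s * fps))
    for i0, i1 in _bool_runs(mask):
        if i1 - i0 >= need:
            out[i0:i1] = True
    return out


def _merge_short_runs(labels: np.ndarray, fps: float,
                      min_s: dict[str, float]) -> np.ndarray:
    """Relabel runs shorter than their state minimum to the longer neighbor."""
    labels = labels.copy()
    changed = True
    while changed:
        changed = False
        runs = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                runs.append((start, i, labels[start]))
                start = i
        for k, (i0, i1, lab) in enumerate(runs):
            if (i1 - i0) / fps >= min_s.get(lab, 0.0) or len(runs) == 1:
                continue
            left = runs[k - 1] if k > 0 else None
            right = runs[k + 1] if k + 1 < len(runs) else None
            if left and (not right or (left[1] - left[0]) >= (right[1] - right[0])):
                labels[i0:i1] = left[2]
            elif right:
                labels[i0:i1] = right[2]
            changed = True
            break
    return labels


def classify_behavior(track: PoseTrack, **params) -> IntervalList:
    """Functional wrapper over :class:`BehaviorClassifier`."""
    return BehaviorClassifier(**params).predict_bouts(track)


# ---------------------------------------------------------------------------
# Sleep staging
# ---------------------------------------------------------------------------

def theta_delta_ratio(rec: Recording, t0: float, t1: float,
                      usable: IntervalList | None = None,
                      theta: Band = Band("theta", 6, 10),
                      delta: Band = Band("delta", 2, 5),
                      window_s: float = 2.0) -> float:
    """Theta:delta band-power ratio of the SWD-masked window [t0, t1)."""
    pieces = [Interval(t0, t1, "usable")]
    if usable is not None:
        pieces = [Interval(max(iv.t0, t0), min(iv.t1, t1), "usable")
                  for iv in usable if min(iv.t1, t1) - max(iv.t0, t0) >= window_s]
        if not pieces:
            return np.nan
    try:
        spec = compute_psd(rec, IntervalList(pieces, validate=False), window_s=window_s)
    except ValueError:
        return np.nan
    dp = band_power(spec, delta)
    if dp == 0:
        log.warning("zero delta power in (%0.1f, %0.1f); ratio set to inf", t0, t1)
        return np.inf
    return band_power(spec, theta) / dp


class SleepStager(BaseEstimator):
    """REM/NREM staging of sleep bouts from the theta:delta power ratio.

    Sleep bouts are cut into ``epoch_s`` epochs; each epoch's SWD-masked
    theta:delta ratio is median-smoothed over ``smooth_epochs`` epochs and
    thresholded: ratio > tau -> REM (theta-dominant), else NREM. By default
    tau adapts per recording as mean + 1 SD of the within-sleep log10
    ratio (the ratio is bimodal and roughly log-normal within stages, so
    the log scale separates the modes and is EEG-gain-invariant); pass a
    numeric ``tau`` to override. Stage runs are merged up to the per-stage
    minimum durations, and a sleep bout shorter than one epoch is NREM.
    """

    def __init__(self, epoch_s: float = 5.0, tau: float | str = "adaptive",
                 smooth_epochs: int = 3, min_rem_s: float = 10.0,
                 min_nrem_s: float = 15.0, psd_window_s: float = 2.0):
        self.epoch_s = epoch_s
        self.tau = tau
        self.smooth_epochs = smooth_epochs
        self.min_rem_s = min_rem_s
        self.min_nrem_s = min_nrem_s
        self.psd_window_s = psd_window_s

    def stage(self, rec: Recording, sleep_bouts: IntervalList,
              usable: IntervalList | None = None) -> IntervalList:
        per_bout: list[tuple[Interval, np.ndarray, np.ndarray]] = []
        all_ratios: list[float] = []
        for bout in sleep_bouts:
            n_ep = int((bout.t1 - bout.t0) // self.epoch_s)
            if n_ep == 0:
                per_bout.append((bout, np.array([]), np.array([])))
                continue
            starts = bout.t0 + self.epoch_s * np.arange(n_ep)
            ratios = np.array([
                theta_delta_ratio(rec, s, s + self.epoch_s, usable,
                                  window_s=self.psd_window_s)
                for s in starts])
            # epochs fully masked by SWDs: interpolate from neighboring
            # epochs (stages are locally persistent, so the neighbors carry
            # the right stage; a bout-wide fill would mix REM and NREM)
            bad = ~np.isfinite(ratios)
            if bad.any() and not bad.all():
                idx = np.arange(n_ep)
                ratios[bad] = np.interp(idx[bad], idx[~bad], ratios[~bad])
            elif bad.all():
                ratios[:] = 0.0
            k = self.smooth_epochs
            if n_ep >= k and k > 1:
                ratios = sps.medfilt(ratios, k + 1 - k % 2)
            per_bout.append((bout, starts, ratios))
            all_ratios.extend(ratios[ratios > 0])

        if isinstance(self.tau, str):
            tau = _adaptive_tau(np.asarray(all_ratios))
        else:
            tau = float(self.tau)
        self.tau_ = tau

        staged: list[Interval] = []
        for bout, starts, ratios in per_bout:
            if starts.size == 0:
                log.info("sleep bout (%.1f, %.1f) shorter than one epoch -> NREM",
                         bout.t0, bout.t1)
                staged.append(Interval(bout.t0, bout.t1, "NREM"))
                continue
            labels = np.where(ratios > tau, "REM", "NREM").astype(object)
            fps_epoch = 1.0 / self.epoch_s
            labels = _merge_short_runs(labels, fps_epoch,
                                       {"REM": self.min_rem_s, "NREM": self.min_nrem_s})
            # epochs tile the bout; the last epoch absorbs the remainder
            start = 0
            for i in range(1, len(labels) + 1):
                if i == len(labels) or labels[i] != labels[start]:
                    t0 = starts[start]
                    t1 = bout.t1 if i == len(labels) else starts[i]
                    staged.append(Interval(t0, t1, str(labels[start])))
                    start = i
        return IntervalList(staged, validate=False)


def _adaptive_tau(ratios: np.ndarray, min_separation: float = 0.6) -> float:
    """Per-recording REM threshold from the within-sleep ratio distribution.

    The theta:delta ratio is bimodal on a log scale (delta-dominant NREM vs
    theta-dominant REM), so the threshold is the midpoint of a two-means
    split of log10(ratio). If the two cluster means are closer than
    ``min_separation`` decades the night is treated as unimodal
    (NREM-only-like) and the conservative mean + 1 SD rule applies — a
    fixed-fraction rule such as mean + 1 SD alone is fragile because its
    position relative to the REM mode shifts with the REM fraction.
    All statistics are ratio-based, hence EEG-gain-invariant.
    """
    logs = np.log10(ratios[np.isfinite(ratios) & (ratios > 0)])
    if logs.size == 0:
        return np.inf
    lo, hi = float(logs.min()), float(logs.max())
    if lo == hi:
        return float(10 ** (hi + 0.5))
    m1, m2 = lo, hi
    for _ in range(50):
        cut = (m1 + m2) / 2
        lower, upper = logs[logs <= cut], logs[logs > cut]
        if lower.size == 0 or upper.size == 0:
            break
        n1, n2 = float(lower.mean()), float(upper.mean())
        if np.isclose(n1, m1) and np.isclose(n2, m2):
            m1, m2 = n1, n2
            break
        m1, m2 = n1, n2
    if m2 - m1 >= min_separation:
        return float(10 ** ((m1 + m2) / 2))
    return float(10 ** (logs.mean() + logs.std(ddof=0)))


def stage_sleep(rec: Recording, sleep_bouts: IntervalList,
                usable: IntervalList | None = None, **params) -> IntervalList:
    """Functional wrapper over :class:`SleepStager`."""
    return SleepStager(**params).stage(rec, sleep_bouts, usable)


# ---------------------------------------------------------------------------
# Bout metrics and seizure rates
# ---------------------------------------------------------------------------

def bout_metrics(bouts: IntervalList, horizon: tuple[float, float]) -> pd.DataFrame:
    """Hourly bout counts and occupied minutes per state.

    The horizon is split into clock hours from its start. A bout counts
    once toward the hour containing its onset but contributes occupied time
    to every hour it overlaps.
    """
    t_start, t_end = horizon
    n_hours = int(np.ceil((t_end - t_start) / 3600.0))
    states = bouts.labels()
    rows = []
    for hour in range(max(n_hours, 0)):
        h0, h1 = t_start + 3600.0 * hour, min(t_start + 3600.0 * (hour + 1), t_end)
        for state in states:
            count, minutes = 0, 0.0
            for iv in bouts.with_label(state):
                if h0 <= iv.t0 < h1:
                    count += 1
                overlap = min(iv.t1, h1) - max(iv.t0, h0)
                if overlap > 0:
                    minutes += overlap / 60.0
            rows.append({"hour": hour, "state": state, "bouts_per_hour": count,
                         "minutes_per_hour": minutes})
    return pd.DataFrame(rows, columns=["hour", "state", "bouts_per_hour",
                                       "minutes_per_hour"])


def seizure_rate_by_stage(events: IntervalList, staged: IntervalList) -> pd.DataFrame:
    """Per-stage seizure counts, stage hours, and rates (events/h).

    An event belongs to the stage whose bout contains its onset; events
    starting outside every staged bout are tallied as ``unstaged`` and
    excluded from rates.
    """
    stages = staged.labels()
    rows = []
    onsets = np.array([iv.t0 for iv in events])
    assigned = np.zeros(len(events), dtype=bool)
    for stage in stages:
        hours = staged.with_label(stage).total_duration() / 3600.0
        count = 0
        for k, t in enumerate(onsets):
            for iv in staged.with_label(stage):
                if iv.t0 <= t < iv.t1:
                    count += 1
                    assigned[k] = True
                    break
        rate = count / hours if hours > 0 else np.nan
        rows.append({"stage": stage, "n_events": count, "hours": hours,
                     "rate_per_hour": rate})
    rows.append({"stage": "unstaged", "n_events": int((~assigned).sum()),
                 "hours": np.nan, "rate_per_hour": np.nan})
    return pd.DataFrame(rows, columns=["stage", "n_events", "hours", "rate_per_hour"])
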