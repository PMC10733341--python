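import numpy as np
import pandas as pd
import pytest

from cagewave import PoseTrack, Recording, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sine_recording(freq_hz: float, amp: float = 1.0, fs: float = 200.0,
                   duration_s: float = 60.0, **meta) -> Recording:
    t = np.arange(int(duration_s * fs)) / fs
    return Recording(amp * np.sin(2 * np.pi * freq_hz * t), fs=fs, **meta)


def make_pose(n_frames: int, fps: float = 30.0, px_per_cm: float = 10.0,
              keypoints=("snout", "body_center", "tailbase"),
              xy=None, likelihood=None) -> PoseTrack:
    """Static pose track unless per-keypoint xy arrays are given."""
    tt = np.arange(n_frames) / fps
    data = {}
    for bp in keypoints:
        if xy is not None and bp in xy:
            x, y = xy[bp]
        else:
            x, y = np.full(n_frames, 150.0), np.full(n_frames, 150.0)
        lik = likelihood[bp] if likelihood and bp in likelihood else np.ones(n_frames)
        data[(bp, "x")] = np.asarray(x, dtype=float)
        data[(bp, "y")] = np.asarray(y, dtype=float)
        data[(bp, "likelihood")] = np.asarray(lik, dtype=float)
    df = pd.DataFrame(data)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return PoseTrack(frame_times=tt, data=df, px_per_cm=px_per_cm)


@pytest.fixture
def short_session():
    """A 10-minute KO session with a flat 20/h SWD rate, plus ground truth."""
    from cagewave import sample_states, synth_eeg

    rates = {s: 20.0 for s in ("REM", "NREM", "rest", "walk", "groom", "dig")}
    cfg = SimConfig(session_s=600.0, genotype="KO", swd_rate_per_hour=rates)
    behavior, stages = sample_states(cfg, 42)
    rec, truth = synth_eeg(behavior, stages, cfg, 43)
    return rec, truth, cfg
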