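"""End-to-end orchestration: simulate/load -> SWD detect -> mask ->
classify/stage -> spectra + PAC -> tidy summaries.

Group-level inference (the mixed models a study would fit) is deliberately
exported, not implemented: the pipeline's scientific surface is the upstream
computation, and :func:`group_summarize` attaches hierarchical-bootstrap CIs
(resampling animals, then bouts) to schema-stable tidy tables for external
statistics.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (DEFAULT_BANDS, Band, IntervalList, PoseTrack,
                 read_eeg, read_pose_table, write_intervals)
from .spectral import compute_psd, harmonic_check, pac
from .states import (BehaviorClassifier, SleepStager, bout_metrics,
                     seizure_rate_by_stage)
from .swd import SWDDetector, remove_swd
from .simulate import SimConfig, simulate_session

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``eeg_path`` (plus optionally ``pose_path``) or ``sim`` must be
    set; every downstream estimator parameter can be overridden through the
    three params dicts.
    """

    out_dir: str | Path = "cagewave_out"
    seed: int = 0
    eeg_path: str | Path | None = None
    fs_hint: float | None = None
    pose_path: str | Path | None = None
    px_per_cm: float = 10.0
    fps: float = 30.0
    sim: SimConfig | None = None
    bands: tuple[Band, ...] = DEFAULT_BANDS
    swd_pad_s: float = 0.5
    detector_params: dict = field(default_factory=dict)
    behavior_params: dict = field(default_factory=dict)
    stager_params: dict = field(default_factory=dict)
    pac_n_surrogates: int = 200


OUTPUT_FILES = ("swd_events.csv", "usable_segments.csv", "behavior_bouts.csv",
                "sleep_stages.csv", "band_powers.csv", "pac.csv",
                "hourly_summaries.csv", "stage_rates.csv", "manifest.json")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a manifest dict with per-stage counts.

    Outputs (CSV/JSON) land in ``cfg.out_dir``; a stage failure raises after
    writing a ``.partial`` marker so partial outputs stay auditable. EEG-only
    inputs skip the behavior outputs gracefully.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.write_text("running")
    counts: dict = {}
    try:
        # --- inputs -----------------------------------------------------
        pose: PoseTrack | None = None
        if cfg.sim is not None:
            rec, pose, truth = simulate_session(cfg.sim, cfg.seed)
            log.info("simulated session: %.0f s, %d SWDs", rec.duration,
                     len(truth.swd_events))
        else:
            if cfg.eeg_path is None:
                raise ValueError("RunConfig needs eeg_path or sim")
            rec = read_eeg(cfg.eeg_path, fs_hint=cfg.fs_hint)
            if cfg.pose_path is not None:
                pose = read_pose_table(cfg.pose_path, px_per_cm=cfg.px_per_cm,
                                       fps=cfg.fps)

        # --- SWD detection and masking ----------------------------------
        detector = SWDDetector(**cfg.detector_params)
        events, review = detector.detect(rec)
        usable = remove_swd(rec, events, pad_s=cfg.swd_pad_s)
        counts["n_swd_candidates"] = len(review)
        counts["n_swd_accepted"] = len(events)
        counts["usable_s"] = usable.total_duration()
        write_intervals(events, out / "swd_events.csv")
        review.to_csv(out / "swd_review.csv", index=False)
        write_intervals(usable, out / "usable_segments.csv")

        # --- behavior and staging ---------------------------------------
        horizon = (rec.start_time, rec.start_time + rec.duration)
        if pose is not None:
            behavior = BehaviorClassifier(**cfg.behavior_params).predict_bouts(pose)
            write_intervals(behavior, out / "behavior_bouts.csv")
            sleep_bouts = behavior.with_label("sleep")
            stager = SleepStager(**cfg.stager_params)
            stages = stager.stage(rec, sleep_bouts, usable)
            write_intervals(stages, out / "sleep_stages.csv")
            counts["n_behavior_bouts"] = len(behavior)
            counts["n_stage_bouts"] = len(stages)
            state_bouts = IntervalList(
                [iv for iv in behavior if iv.label != "sleep"] + list(stages),
                validate=False)
        else:
            log.info("no pose input: behavior outputs skipped")
            counts["behavior"] = "skipped (EEG-only input)"
            behavior = stages = None
            state_bouts = IntervalList([])
            write_intervals(IntervalList([]), out / "behavior_bouts.csv")
            write_intervals(IntervalList([]), out / "sleep_stages.csv")

        # --- spectra, band powers, PAC ----------------------------------
        from .spectral import band_power, bout_band_powers

        if len(state_bouts):
            powers = bout_band_powers(rec, state_bouts, usable, cfg.bands)
        else:
            spec = compute_psd(rec, usable)
            powers = pd.DataFrame(
                [{"bout_id": 0, "t0": horizon[0], "t1": horizon[1],
                  "state": "all", "animal_id": rec.animal_id,
                  "genotype": rec.genotype, "band": b.name,
                  "power": band_power(spec, b)}
                 for b in cfg.bands])
        powers.to_csv(out / "band_powers.csv", index=False)
        counts["n_band_power_samples"] = len(powers)

        pac_rows = []
        for amp_name, amp_band in (("slow_gamma", Band("slow_gamma", 25, 45)),
                                   ("delta", Band("delta", 2, 5))):
            try:
                res = pac(rec, usable, phase_band=Band("theta", 6, 10),
                          amp_band=amp_band,
                          n_surrogates=cfg.pac_n_surrogates, seed=cfg.seed)
                pac_rows.append({
                    "phase_band": "theta", "amp_band": amp_name, "mi": res.mi,
                    "surrogate_mean": res.surrogate_mean,
                    "surrogate_sd": res.surrogate_sd, "z": res.z,
                    "significant": res.significant,
                    "n_surrogates": res.n_surrogates, "seed": res.seed})
            except ValueError as exc:
                log.warning("PAC (%s) skipped: %s", amp_name, exc)
        pd.DataFrame(pac_rows).to_csv(out / "pac.csv", index=False)

        spec_all = compute_psd(rec, usable)
        spec_all.to_frame().to_csv(out / "spectrum.csv", index=False)
        counts["harmonic_check"] = harmonic_check(spec_all)

        # --- summaries ---------------------------------------------------
        if behavior is not None:
            hourly = pd.concat([bout_metrics(behavior, horizon),
                                bout_metrics(stages, horizon)],
                               ignore_index=True)
            rates = seizure_rate_by_stage(events, stages)
        else:
            hourly = pd.DataFrame(columns=["hour", "state", "bouts_per_hour",
                                           "minutes_per_hour"])
            rates = pd.DataFrame(columns=["stage", "n_events", "hours",
                                          "rate_per_hour"])
        hourly.to_csv(out / "hourly_summaries.csv", index=False)
        rates.to_csv(out / "stage_rates.csv", index=False)

        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "counts": counts,
            "files": {p.name: hashlib.md5(p.read_bytes()).hexdigest()
                      for p in sorted(out.glob("*.csv"))},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True, default=str))
    except Exception:
        marker.write_text("failed")
        raise
    marker.unlink()
    return manifest


def group_summarize(powers: pd.DataFrame, n_boot: int = 1000, alpha: float = 0.05,
                    seed: int = 0) -> pd.DataFrame:
    """Hierarchical-bootstrap group table over band-power samples.

    For each (genotype, state, band): the group mean of per-animal means,
    with a 95% percentile CI from resampling animals first, then each
    resampled animal's bouts. Single-animal groups get a point estimate and
    a CI marked unavailable (NaN).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (geno, state, band), grp in powers.groupby(["genotype", "state", "band"],
                                                   sort=True):
        animals = sorted(grp["animal_id"].unique())
        per_animal = grp.groupby("animal_id")["power"]
        point = float(per_animal.mean().mean())
        if len(animals) < 2:
            lo = hi = np.nan
        else:
            by_animal = {a: per_animal.get_group(a).to_numpy() for a in animals}
            boots = np.empty(n_boot)
            for b in range(n_boot):
                picked = rng.choice(animals, size=len(animals), replace=True)
                means = [by_animal[a][rng.integers(0, len(by_animal[a]),
                                                   len(by_animal[a]))].mean()
                         for a in picked]
                boots[b] = np.mean(means)
            lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        rows.append({"genotype": geno, "state": state, "band": band,
                     "n_animals": len(animals), "n_bouts": len(grp),
                     "mean_power": point, "ci_lo": float(lo), "ci_hi": float(hi)})
    return pd.DataFrame(rows)
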