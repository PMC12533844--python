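"""End-to-end orchestration: simulate -> train -> call -> assay.

One :class:`RunConfig` drives an entire run.  Each stage writes its
outputs under the run directory; a manifest records the config snapshot,
software version, and a SHA-256 hash of every output file, so a rerun
with identical config and seeds is verifiably bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assays, classify, features, kinematics, smoothing, synthetic
from .pose_io import StimulusEvent, read_pose_track, write_labels, write_pose_track

logger = logging.getLogger(__name__)

STAGES = ("simulate", "train", "calls", "respond", "summarize")


class DependencyError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All knobs of an end-to-end run, with the pipeline's fixed defaults.

    Defaults carry the pipeline constants: 40-frame windows, k = 9
    clusters, 90/10 split, 0.95 PCA variance with seed 2023, 2 mm/s and
    5-frame speed-bout thresholds, >5-frame call bouts, 160 fps.
    """

    out_dir: str = "fishbout_run"
    plate_format: int = 24
    n_fish: int = 4
    seconds: float = 10.0
    fps: float = 160.0
    schedule: str = "random"
    stimulus: str | None = None  # "acoustic" | "visual" | None
    stimulus_onset_s: float = 5.0
    window: int = 40
    n_per_class: int = 100
    train_frac: float = 0.9
    k_clusters: int = 9
    speed_threshold: float = 2.0
    min_speed_frames: int = 5
    min_run: int = 5
    sim_seed: int = 1
    split_seed: int = 7
    rfc_seed: int = 11
    pca_seed: int = classify.PCA_SEED
    noise_sigma_mm: float = 0.008

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    Stage outputs land under ``config.out_dir``; the manifest (also written
    as ``manifest.json``) maps every output file to its SHA-256 hash and
    names the config hash that produced it.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "software": f"fishbout {__version__}",
        "stages": {},
        "hashes": {},
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.monotonic()
        paths = _STAGE_FNS[stage](config, out, state)
        manifest["stages"][stage] = {
            "seconds": round(time.monotonic() - t0, 3),
            "outputs": [str(p) for p in paths],
        }
        for p in paths:
            manifest["hashes"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> list[Path]:
    tracks_dir = out / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    events = []
    if config.stimulus:
        events = [StimulusEvent(config.stimulus, config.stimulus_onset_s)]
    paths = []
    state["tracks"] = []
    for i in range(config.n_fish):
        cfg = synthetic.SyntheticConfig(
            fps=config.fps,
            seconds=config.seconds,
            plate_format=config.plate_format,
            noise_sigma_mm=config.noise_sigma_mm,
        )
        track, labels = synthetic.generate_track(
            config.schedule,
            cfg,
            seed=config.sim_seed + i,
            events=events,
            well_id=f"fish{i:03d}",
        )
        p = write_pose_track(track, tracks_dir / f"fish{i:03d}.h5")
        lp = write_labels(labels, tracks_dir / f"fish{i:03d}_truth.csv")
        state["tracks"].append(track)
        paths += [p, lp]
    return paths


def _stage_train(config: RunConfig, out: Path, state: dict) -> list[Path]:
    cfg = synthetic.SyntheticConfig(
        fps=config.fps,
        plate_format=config.plate_format,
        noise_sigma_mm=config.noise_sigma_mm,
    )
    windows, labels = synthetic.generate_labeled_dataset(
        cfg, config.n_per_class, seed=config.sim_seed
    )
    fm = features.featurize(
        [
            features.BehaviorWindow(start=i, coords=w, aligned=True)
            for i, w in enumerate(windows)
        ],
        plate_format=config.plate_format,
    )
    X_tr, X_te, y_tr, y_te = classify.split_dataset(
        fm.vectors, labels, config.train_frac, seed=config.split_seed
    )
    bundle = classify.train(
        X_tr,
        y_tr,
        classify.ClassSet.for_plate(config.plate_format),
        stats=(fm.norm_max, fm.norm_mean),
        pca_seed=config.pca_seed,
        rfc_seed=config.rfc_seed,
    )
    report = classify.evaluate(bundle, X_te, y_te)
    bdir = bundle.save(out / "bundle")
    (out / "evaluation.json").write_text(
        json.dumps(
            {
                "macro_f1": report.macro_f1,
                "per_class_f1": report.per_class_f1,
                "confusion": report.confusion.to_dict(),
            },
            indent=1,
        )
    )
    state["bundle"] = bundle
    return [bdir / "bundle.json", bdir / "pca.joblib", bdir / "forest.joblib",
            out / "evaluation.json"]


def _load_tracks(config: RunConfig, out: Path, state: dict):
    if "tracks" not in state:
        tracks_dir = out / "tracks"
        if not tracks_dir.exists():
            raise DependencyError(
                "no tracks found; run the 'simulate' stage first"
            )
        state["tracks"] = [
            read_pose_track(p) for p in sorted(tracks_dir.glob("fish*.h5"))
        ]
    return state["tracks"]


def _stage_calls(config: RunConfig, out: Path, state: dict) -> list[Path]:
    if "bundle" not in state:
        bdir = out / "bundle"
        if not (bdir / "bundle.json").exists():
            raise DependencyError(
                "no classifier bundle; run the 'train' stage first"
            )
        state["bundle"] = classify.ClassifierBundle.load(bdir)
    bundle = state["bundle"]
    calls_dir = out / "calls"
    calls_dir.mkdir(exist_ok=True)
    paths = []
    state["calls"] = []
    state["bouts"] = []
    for track in _load_tracks(config, out, state):
        fl = call_frames(bundle, track, width=config.window)
        series = kinematics.kinematic_series(track)
        bouts = kinematics.annotate_bouts(
            smoothing.extract_bouts(
                fl, track.fps, min_run=config.min_run, fish_id=track.well_id
            ),
            series,
        )
        state["calls"].append((track, fl))
        state["bouts"].append((track, bouts))
        cp = calls_dir / f"{track.well_id}_calls.csv"
        pd.DataFrame(
            {
                "frame": np.arange(fl.n_frames),
                "label": fl.labels,
                "margin": fl.margins,
            }
        ).to_csv(cp, index=False)
        bp = calls_dir / f"{track.well_id}_bouts.csv"
        pd.DataFrame(
            [
                {
                    "label": b.label,
                    "start_frame": b.start,
                    "end_frame": b.end,
                    "duration_ms": b.duration_ms,
                    "max_speed_mm_s": b.max_speed,
                    "max_abs_dheading_deg": b.max_abs_dheading,
                }
                for b in bouts
            ]
        ).to_csv(bp, index=False)
        paths += [cp, bp]
    return paths


def _stage_respond(config: RunConfig, out: Path, state: dict) -> list[Path]:
    if "calls" not in state:
        raise DependencyError("no calls computed; run the 'calls' stage first")
    records = []
    for track, fl in state["calls"]:
        for ev in track.events:
            records.append(
                {
                    "fish_id": track.well_id,
                    "trial_id": "t0",
                    "stimulus": ev.kind,
                    "responded": assays.trial_response(fl, ev, track.fps),
                }
            )
    if not records:
        logger.warning("respond stage: no stimulus events on any track")
        table = pd.DataFrame(
            columns=["fish_id", "trial_id", "stimulus", "responded"]
        )
        rates = {}
    else:
        table = assays.make_response_table(records)
        trial_rate, fish_rate = assays.response_rates(table)
        rates = {"trial_rate": trial_rate, "fish_rate": fish_rate}
    tp = out / "responses.csv"
    table.to_csv(tp, index=False)
    rp = out / "response_rates.json"
    rp.write_text(json.dumps(rates, indent=1))
    return [tp, rp]


def _stage_summarize(config: RunConfig, out: Path, state: dict) -> list[Path]:
    if "bouts" not in state:
        raise DependencyError("no bouts computed; run the 'calls' stage first")
    summaries = {}
    for track, bouts in state["bouts"]:
        summaries[track.well_id] = assays.spontaneous_summary(
            bouts, track.n_frames, track.fps
        )
    sp = out / "spontaneous_summary.json"
    sp.write_text(json.dumps(summaries, indent=1))
    return [sp]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "train": _stage_train,
    "calls": _stage_calls,
    "respond": _stage_respond,
    "summarize": _stage_summarize,
}


def call_frames(
    bundle: classify.ClassifierBundle,
    track,
    width: int | None = None,
) -> smoothing.FrameLabels:
    """Track -> per-frame behavior calls: featurize, predict, majority-vote."""
    width = width or bundle.width
    fm = features.featurize_track(
        track, stats=(bundle.norm_max, bundle.norm_mean), width=width
    )
    labels, _ = classify.predict(bundle, fm)
    return smoothing.majority_vote(
        labels,
        fm.window_starts,
        width,
        track.n_frames,
        bundle.class_set.labels,
    )
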