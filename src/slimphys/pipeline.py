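"""End-to-end orchestration: simulate -> track -> count -> periodicity.

A single YAML config drives every stage; one global seed fans out to
per-stage, per-acquisition sub-seeds via ``numpy.random.SeedSequence``
spawning in a fixed order, so each stage is independently reproducible.
A manifest records inputs, outputs and row counts per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .counting import (
    BrightnessCalibration,
    calibrate_from_tracks,
    stoichiometries_from_tracks,
)
from .periodicity import estimate_periodicity
from .synthetic import SlimfieldSimConfig, simulate_image_stack
from .tracking import TrackingParams, track_stack

logger = logging.getLogger("slimphys.pipeline")

KNOWN_SECTIONS = {"seed", "simulate", "tracking", "counting", "periodicity"}

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, exit_code: int = EXIT_DATA_ERROR):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
        self.exit_code = exit_code


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def stage_seeds(seed: int, n_acquisitions: int) -> dict:
    """Fan a global seed out to per-stage/per-acquisition sub-seeds.

    Spawn order is fixed: one child per acquisition for simulation,
    then one child for the periodicity bootstrap.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_acquisitions + 1)
    return {
        "simulate": [int(c.generate_state(1)[0]) for c in children[:n_acquisitions]],
        "bootstrap": int(children[n_acquisitions].generate_state(1)[0]),
    }


def run_all(config: dict, out_dir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Config sections: ``seed`` (int), ``simulate`` (SlimfieldSimConfig
    fields plus ``n_acquisitions``), ``tracking`` (TrackingParams
    fields), ``counting`` (``calibration``: "self" | path | {brightness,
    uncertainty, n_steps}; ``min_steps``), ``periodicity``
    (``kernel_width``, ``pairwise``, ``bootstrap``).
    """
    unknown = sorted(set(config) - KNOWN_SECTIONS)
    if unknown:
        raise PipelineError(
            "config", f"unknown config key(s): {', '.join(unknown)}", EXIT_CONFIG_ERROR
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    sim_cfg = dict(config.get("simulate", {}))
    n_acq = int(sim_cfg.pop("n_acquisitions", 1))
    seeds = stage_seeds(seed, n_acq)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "tool_version": _version(),
        "stages": [],
    }

    # --- simulate ---------------------------------------------------
    stack_paths, mask_paths, truths = [], [], []
    try:
        for a in range(n_acq):
            cfg = SlimfieldSimConfig(**sim_cfg, seed=seeds["simulate"][a])
            stack, mask, truth = simulate_image_stack(cfg)
            sp = out_dir / f"stack_{a:03d}.tif"
            mp = out_dir / f"mask_{a:03d}.tif"
            sio.write_stack(stack, sp)
            sio.write_mask(mask, mp)
            truth.summary_frame().assign(acquisition_id=a).to_csv(
                out_dir / f"truth_{a:03d}.csv", index=False
            )
            stack_paths.append(sp)
            mask_paths.append(mp)
            truths.append(truth)
            logger.info("simulated acquisition %d: %d complexes", a, cfg.n_complexes)
    except (TypeError, ValueError) as exc:
        raise PipelineError("simulate", str(exc), EXIT_CONFIG_ERROR) from exc
    manifest["stages"].append(
        {
            "stage": "simulate",
            "outputs": [str(p) for p in stack_paths + mask_paths],
            "n_acquisitions": n_acq,
        }
    )

    # --- track ------------------------------------------------------
    track_cfg = dict(config.get("tracking", {}))
    extend_frames = int(track_cfg.pop("extend_frames", 60))
    try:
        params = TrackingParams(**track_cfg)
    except (TypeError, ValueError) as exc:
        raise PipelineError("track", str(exc), EXIT_CONFIG_ERROR) from exc
    frames = []
    frame_interval = None
    for a, (sp, mp) in enumerate(zip(stack_paths, mask_paths)):
        if not sp.exists():
            raise PipelineError("track", f"missing upstream file {sp}")
        stack = sio.read_stack(sp)
        mask = sio.read_mask(mp)
        frame_interval = stack.frame_interval
        tracks = track_stack(stack, mask, params, extend_frames=extend_frames, log=logger.debug)
        # acquisition-local ids -> globally unique
        tracks["track_id"] = tracks["track_id"].astype(int) + a * 1_000_000
        tracks["acquisition_id"] = a
        frames.append(tracks)
        logger.info("acquisition %d: %d tracks", a, tracks["track_id"].nunique())
    track_table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=sio.TRACK_COLUMNS + ["acquisition_id"])
    )
    tracks_path = out_dir / "tracks.csv"
    with open(tracks_path, "w") as fh:
        fh.write("# slimphys track table v1 (+acquisition_id)\n")
        track_table.to_csv(fh, index=False)
    manifest["stages"].append(
        {
            "stage": "track",
            "outputs": [str(tracks_path)],
            "n_rows": int(len(track_table)),
            "n_tracks": int(track_table["track_id"].nunique()) if len(track_table) else 0,
            "params": asdict(params),
        }
    )

    # --- count ------------------------------------------------------
    count_cfg = dict(config.get("counting", {}))
    cal_spec = count_cfg.get("calibration", "self")
    min_steps = int(count_cfg.get("min_steps", 20))
    if cal_spec == "self":
        try:
            calibration = calibrate_from_tracks(track_table, min_steps=min_steps)
        except Exception as exc:
            raise PipelineError("count", f"self-calibration failed: {exc}") from exc
    elif isinstance(cal_spec, dict):
        calibration = BrightnessCalibration(
            brightness=float(cal_spec["brightness"]),
            uncertainty=float(cal_spec.get("uncertainty", 0.0)),
            n_steps=int(cal_spec.get("n_steps", 1)),
        )
    else:
        cal_path = Path(cal_spec)
        if not cal_path.exists():
            raise PipelineError("count", f"missing calibration file {cal_path}")
        calibration = BrightnessCalibration.from_dict(sio.read_result(cal_path))
    sio.write_result(calibration.to_dict(), out_dir / "calibration.json")
    stoich = stoichiometries_from_tracks(
        track_table, calibration, frame_interval or 0.010, log=logger.debug
    )
    stoich_path = out_dir / "stoichiometries.csv"
    sio.write_stoichiometries(stoich, stoich_path)
    manifest["stages"].append(
        {
            "stage": "count",
            "outputs": [str(stoich_path), str(out_dir / "calibration.json")],
            "n_rows": int(len(stoich)),
            "brightness": calibration.brightness,
            "params": {"calibration": str(cal_spec), "min_steps": min_steps},
        }
    )

    # --- periodicity ------------------------------------------------
    per_cfg = dict(config.get("periodicity", {}))
    # group_size pools consecutive stacks into one acquisition for the
    # peak-interval grouping (a field acquisition can hold several ROIs)
    group_size = max(1, int(per_cfg.get("group_size", 1)))
    samples_by_acq: dict = {}
    for acq, grp in stoich.groupby("acquisition_id"):
        samples_by_acq.setdefault(int(acq) // group_size, []).extend(
            grp["stoichiometry"].tolist()
        )
    analysis = estimate_periodicity(
        samples_by_acq,
        kernel_width=float(per_cfg.get("kernel_width", 0.7)),
        pairwise=bool(per_cfg.get("pairwise", True)),
        n_bootstrap=int(per_cfg.get("bootstrap", 1000)),
        seed=seeds["bootstrap"],
    )
    result_path = out_dir / "periodicity.json"
    payload = {
        "status": analysis["status"],
        "n_tracks": analysis["n_tracks"],
        "kernel_width": per_cfg.get("kernel_width", 0.7),
        "seed": seed,
    }
    if analysis["result"] is not None:
        payload.update(analysis["result"].to_dict())
        payload["mean_stoichiometry"] = analysis["mean_stoichiometry"]
    sio.write_result(payload, result_path)
    manifest["stages"].append(
        {
            "stage": "periodicity",
            "outputs": [str(result_path)],
            "status": analysis["status"],
            "params": {
                "kernel_width": float(per_cfg.get("kernel_width", 0.7)),
                "pairwise": bool(per_cfg.get("pairwise", True)),
                "bootstrap": int(per_cfg.get("bootstrap", 1000)),
                "group_size": group_size,
            },
        }
    )

    manifest_path = out_dir / "manifest.json"
    sio.write_result(manifest, manifest_path)
    for stage in manifest["stages"]:
        for p in stage["outputs"]:
            if not Path(p).exists():  # pragma: no cover - invariant
                raise PipelineError(stage["stage"], f"declared output missing: {p}")
    return manifest


def _version() -> str:
    from . import __version__

    return __version__
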