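"""Canonical demo configuration: pentamer-forming assemblies imaged at
Slimfield-like settings, plus a one-call replicate runner.

The defaults mimic the biological target the package was built around:
unit of 5 tagged subunits, a 1x/2x/3x assembly mixture, 56
photoelectrons/frame/molecule, per-frame bleaching 0.03 and background
noise giving roughly a 0.7-molecule stoichiometry spread.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .counting import calibrate_from_tracks, stoichiometries_from_tracks
from .periodicity import estimate_periodicity
from .synthetic import SlimfieldSimConfig, simulate_image_stack
from .tracking import TrackingParams, track_stack

DEMO_SIM_KWARGS = dict(
    unit_size=5,
    multiple_weights={1: 0.5, 2: 0.3, 3: 0.2},
    maturation_prob=1.0,
    brightness=56.0,
    bleach_prob=0.03,
    n_complexes=14,
    diffusion_coeff=0.01,
    frame_count=250,
    image_shape=(100, 100),
    roi=(8, 8, 92, 92),
    background_rate=5.0,
    read_noise_sd=2.0,
    placement="grid",
)

DEMO_TRACKING = dict(
    smooth_sigma=1.5,
    threshold_sd=2.5,
    threshold_method="median_mad",
    min_track_length=10,
)

DEMO_EXTEND_FRAMES = 60

# stacks (pyrenoids) pooled into one acquisition for the peak-interval
# analysis: an acquisition images a field holding several pyrenoids
DEMO_GROUP_SIZE = 3


def demo_sim_config(seed: int, unit_size: int = 5, **overrides) -> SlimfieldSimConfig:
    kwargs = dict(DEMO_SIM_KWARGS, unit_size=unit_size, **overrides)
    return SlimfieldSimConfig(**kwargs, seed=seed)


def demo_pipeline_config(seed: int = 42, n_stacks: int = 24) -> dict:
    """Config dict for ``slimphys pipeline run`` reproducing the demo."""
    sim = dict(DEMO_SIM_KWARGS)
    sim["image_shape"] = list(sim["image_shape"])
    sim["roi"] = list(sim["roi"])
    sim["n_acquisitions"] = n_stacks
    return {
        "seed": seed,
        "simulate": sim,
        "tracking": dict(DEMO_TRACKING, extend_frames=DEMO_EXTEND_FRAMES),
        "counting": {"calibration": "self", "min_steps": 20},
        "periodicity": {
            "kernel_width": 0.7,
            "pairwise": True,
            "bootstrap": 1000,
            "group_size": DEMO_GROUP_SIZE,
        },
    }


def run_demo_replicate(
    seed: int,
    n_stacks: int = 24,
    unit_size: int = 5,
    n_bootstrap: int = 200,
    group_size: int = DEMO_GROUP_SIZE,
    sim_overrides: dict | None = None,
    calib_kwargs: dict | None = None,
    kernel_width: float = 0.7,
) -> dict:
    """Simulate, track, self-calibrate, count and estimate periodicity.

    ``n_stacks`` pyrenoid ROI stacks are simulated; ``group_size``
    consecutive stacks form one acquisition for the peak-interval
    grouping.  Returns a dict with ``calibration``
    (:class:`BrightnessCalibration`), ``stoichiometries`` (DataFrame),
    ``tracks`` and the periodicity ``analysis`` dict from
    :func:`estimate_periodicity`.
    """
    params = TrackingParams(**DEMO_TRACKING)
    frames = []
    root = np.random.SeedSequence(seed)
    acq_seeds = [int(c.generate_state(1)[0]) for c in root.spawn(n_stacks + 1)]
    for a in range(n_stacks):
        cfg = demo_sim_config(
            acq_seeds[a], unit_size=unit_size, **(sim_overrides or {})
        )
        stack, mask, _ = simulate_image_stack(cfg)
        tracks = track_stack(stack, mask, params, extend_frames=DEMO_EXTEND_FRAMES)
        tracks["track_id"] = tracks["track_id"].astype(int) + a * 1_000_000
        tracks["acquisition_id"] = a // group_size
        frames.append(tracks)
    tracks = pd.concat(frames, ignore_index=True)
    calibration = calibrate_from_tracks(tracks, **(calib_kwargs or {}))
    stoich = stoichiometries_from_tracks(tracks, calibration, 0.010)
    samples = {
        acq: grp["stoichiometry"].tolist()
        for acq, grp in stoich.groupby("acquisition_id")
    }
    analysis = estimate_periodicity(
        samples,
        kernel_width=kernel_width,
        n_bootstrap=n_bootstrap,
        seed=acq_seeds[n_stacks],
    )
    return {
        "calibration": calibration,
        "tracks": tracks,
        "stoichiometries": stoich,
        "analysis": analysis,
    }
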