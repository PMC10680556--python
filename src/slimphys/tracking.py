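"""Spot detection, intensity quantification, candidate filtering and
nearest-neighbor linking.

The quantification follows the counting protocol: the summed intensity
of a spot is the sum of all pixel values whose centers lie within
``inner_radius`` (default 5 px) of the sub-pixel centroid, minus the
disc pixel count times the local background mean, where the background
mean and SD are taken over the annulus of pixels strictly more than
``inner_radius`` and at most ``annulus_outer`` (default 8 px) from the
centroid.  Candidates whose summed intensity falls below
``candidate_factor`` (default 0.4) times the annulus SD are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.feature import peak_local_max

from .io import ImageStack, ROIMask, TRACK_COLUMNS


@dataclass
class Spot:
    frame: int
    centroid: tuple[float, float]
    summed_intensity: float
    background_mean: float
    background_sd: float
    roi_label: int
    valid: bool = True


@dataclass
class TrackingParams:
    inner_radius: float = 5.0
    annulus_inner: float = 5.0
    annulus_outer: float = 8.0
    candidate_factor: float = 0.4
    smooth_sigma: float = 1.0
    threshold_sd: float = 2.0  # detection threshold: location + k*scale of masked pixels
    threshold_method: str = "mean_sd"  # or "median_mad" (robust to bright foci)
    max_link_displacement: float = 5.0
    min_track_length: int = 4

    def __post_init__(self) -> None:
        if not self.inner_radius <= self.annulus_inner < self.annulus_outer:
            raise ValueError(
                "need inner_radius <= annulus_inner < annulus_outer; got "
                f"{self.inner_radius}, {self.annulus_inner}, {self.annulus_outer}"
            )
        if self.candidate_factor < 0 or self.min_track_length < 1:
            raise ValueError("candidate_factor >= 0 and min_track_length >= 1 required")
        if self.threshold_method not in ("mean_sd", "median_mad"):
            raise ValueError(f"unknown threshold_method '{self.threshold_method}'")


def _disc_refine(image: np.ndarray, peak: tuple[int, int], radius: float) -> tuple[float, float]:
    """Sub-pixel refinement: intensity centroid over the inner disc.

    Weights are background-floored (disc minimum subtracted) so a
    constant offset does not drag the centroid toward the disc center.
    """
    r, c = peak
    half = int(math.ceil(radius))
    r0, r1 = max(0, r - half), min(image.shape[0], r + half + 1)
    c0, c1 = max(0, c - half), min(image.shape[1], c + half + 1)
    window = image[r0:r1, c0:c1].astype(float)
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    inside = (rows - r) ** 2 + (cols - c) ** 2 <= radius**2
    weights = np.where(inside, window - window[inside].min(), 0.0)
    total = weights.sum()
    if total <= 0:
        return float(r), float(c)
    return (
        float((weights * rows).sum() / total),
        float((weights * cols).sum() / total),
    )


def detect_spots(
    frame_image: np.ndarray,
    mask: np.ndarray | ROIMask | None,
    params: TrackingParams,
    frame: int = 0,
) -> list[Spot]:
    """Detect candidate foci in one frame.

    Local maxima of the Gaussian-smoothed image above ``mean +
    threshold_sd * SD`` of the masked pixels, with maxima closer than
    ``inner_radius`` merged keeping the brighter; centroids refined to
    sub-pixel by intensity center of mass over the inner disc, then
    measured with :func:`measure_spot`.
    """
    image = np.asarray(frame_image, dtype=float)
    if mask is None:
        labels = np.ones(image.shape, dtype=np.int32)
    else:
        labels = mask.labels if isinstance(mask, ROIMask) else np.asarray(mask)
        if labels.shape != image.shape:
            raise ValueError(
                f"mask shape {labels.shape} does not match frame {image.shape}"
            )
    inside = labels > 0
    if not inside.any():
        return []
    smoothed = gaussian_filter(image, params.smooth_sigma) if params.smooth_sigma > 0 else image
    pix = smoothed[inside]
    if params.threshold_method == "median_mad":
        med = np.median(pix)
        scale = 1.4826 * np.median(np.abs(pix - med))
        threshold = med + params.threshold_sd * scale
    else:
        threshold = pix.mean() + params.threshold_sd * pix.std()
    peaks = peak_local_max(
        smoothed,
        min_distance=max(1, int(round(params.inner_radius))),
        threshold_abs=threshold,
        exclude_border=False,
        labels=labels.astype(np.int32),
    )
    spots: list[Spot] = []
    for r, c in peaks:
        centroid = _disc_refine(image, (int(r), int(c)), params.inner_radius)
        rr = min(max(int(round(centroid[0])), 0), image.shape[0] - 1)
        cc = min(max(int(round(centroid[1])), 0), image.shape[1] - 1)
        label = int(labels[rr, cc])
        if label == 0:
            label = int(labels[r, c])
        summed, bg_mean, bg_sd, valid = measure_spot(image, centroid, params)
        spots.append(
            Spot(
                frame=frame,
                centroid=centroid,
                summed_intensity=summed,
                background_mean=bg_mean,
                background_sd=bg_sd,
                roi_label=label,
                valid=valid,
            )
        )
    return spots


def measure_spot(
    frame_image: np.ndarray,
    centroid: tuple[float, float],
    params: TrackingParams,
) -> tuple[float, float, float, bool]:
    """Background-corrected summed intensity at a sub-pixel centroid.

    Returns ``(summed_intensity, background_mean, background_sd,
    valid)``.  Distances are Euclidean from the centroid to pixel
    centers; the disc is ``d <= inner_radius``, the annulus
    ``annulus_inner < d <= annulus_outer``.  Windows are truncated at
    the image edge; an empty annulus flags the measurement invalid.
    """
    image = np.asarray(frame_image, dtype=float)
    r, c = centroid
    half = int(math.ceil(params.annulus_outer)) + 1
    r0, r1 = max(0, int(math.floor(r)) - half), min(image.shape[0], int(math.ceil(r)) + half + 1)
    c0, c1 = max(0, int(math.floor(c)) - half), min(image.shape[1], int(math.ceil(c)) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return 0.0, 0.0, 0.0, False
    window = image[r0:r1, c0:c1]
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    dist = np.hypot(rows - r, cols - c)
    disc = dist <= params.inner_radius
    annulus = (dist > params.annulus_inner) & (dist <= params.annulus_outer)
    n_disc = int(disc.sum())
    n_annulus = int(annulus.sum())
    if n_disc == 0 or n_annulus == 0:
        return 0.0, 0.0, 0.0, False
    bg_mean = float(window[annulus].mean())
    bg_sd = float(window[annulus].std(ddof=0))
    summed = float(window[disc].sum() - n_disc * bg_mean)
    return summed, bg_mean, bg_sd, True


def filter_candidates(spots: list[Spot], params: TrackingParams) -> list[Spot]:
    """Discard candidates with summed intensity below ``candidate_factor
    * background_sd`` (strict ``<`` discards; the boundary is kept)."""
    return [
        s
        for s in spots
        if s.valid and not s.summed_intensity < params.candidate_factor * s.background_sd
    ]


def link_tracks(
    spots_by_frame: list[list[Spot]],
    params: TrackingParams,
) -> pd.DataFrame:
    """Greedy nearest-neighbor frame-to-frame linking.

    Candidate links between consecutive frames are taken in order of
    increasing displacement; pairs beyond ``max_link_displacement``
    start new tracks.  No gap closing: a missed detection ends the
    track.  Tracks shorter than ``min_track_length`` are dropped.
    """
    next_id = 0
    active: dict[int, Spot] = {}  # track_id -> last spot (previous frame)
    rows: list[tuple] = []

    def _emit(track_id: int, spot: Spot) -> None:
        rows.append(
            (
                track_id,
                spot.frame,
                spot.centroid[0],
                spot.centroid[1],
                spot.summed_intensity,
                spot.background_mean,
                spot.background_sd,
                spot.roi_label,
            )
        )

    for spots in spots_by_frame:
        assignments: dict[int, int] = {}  # spot index -> track_id
        if active and spots:
            track_ids = list(active)
            prev = np.array([active[t].centroid for t in track_ids])
            cur = np.array([s.centroid for s in spots])
            d = np.hypot(
                prev[:, None, 0] - cur[None, :, 0], prev[:, None, 1] - cur[None, :, 1]
            )
            order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
            used_tracks: set[int] = set()
            used_spots: set[int] = set()
            for ti, si in order:
                if d[ti, si] > params.max_link_displacement:
                    break
                if ti in used_tracks or si in used_spots:
                    continue
                used_tracks.add(int(ti))
                used_spots.add(int(si))
                assignments[int(si)] = track_ids[int(ti)]
        new_active: dict[int, Spot] = {}
        for si, spot in enumerate(spots):
            tid = assignments.get(si)
            if tid is None:
                tid = next_id
                next_id += 1
            _emit(tid, spot)
            new_active[tid] = spot
        active = new_active

    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    if df.empty:
        return df
    lengths = df.groupby("track_id")["frame"].size()
    keep = lengths[lengths >= params.min_track_length].index
    df = df[df["track_id"].isin(keep)].sort_values(["track_id", "frame"])
    return df.reset_index(drop=True)


def extend_track_traces(
    stack: ImageStack,
    tracks: pd.DataFrame,
    params: TrackingParams,
    extend_frames: int = 50,
    dead_frames: int = 12,
) -> pd.DataFrame:
    """Continue each track's intensity readout past its last detection.

    The summed intensity of a track is measured in every frame, not
    only frames with a detection: after the final linked spot, the
    measurement is repeated at the track's last known position for up
    to ``extend_frames`` frames so the terminal blinking steps
    (including the final drop to background) enter the trace.  While
    residual signal remains (summed intensity above 2x the annulus SD)
    the readout position is re-centered by the disc's intensity
    centroid, capped at 2 px/frame, so a slowly diffusing molecule is
    not measured off-center; with no signal the position freezes.
    Extension stops after ``dead_frames`` consecutive signal-free
    frames — enough to measure the final background plateau without
    accumulating a long pure-noise tail.  Appended rows carry
    ``detected = 0``; no relinking happens here.
    """
    if tracks.empty or extend_frames <= 0:
        out = tracks.copy()
        out["detected"] = 1
        return out
    rows = []
    for tid, grp in tracks.groupby("track_id"):
        grp = grp.sort_values("frame")
        last = grp.iloc[-1]
        f0 = int(last["frame"]) + 1
        pos = (float(last["row"]), float(last["col"]))
        quiet = 0
        for f in range(f0, min(stack.n_frames, f0 + extend_frames)):
            image = stack.pixels[f]
            refined = _disc_refine(
                image,
                (int(round(pos[0])), int(round(pos[1]))),
                params.inner_radius,
            )
            if np.hypot(refined[0] - pos[0], refined[1] - pos[1]) <= 2.0:
                candidate = refined
            else:
                candidate = pos
            summed, bg_mean, bg_sd, valid = measure_spot(image, candidate, params)
            if not valid:
                break
            # noise scale of the disc-summed intensity, not the per-pixel SD
            summed_sd = bg_sd * math.sqrt(math.pi) * params.inner_radius
            if summed > summed_sd:
                pos = candidate  # track residual signal
                quiet = 0
            else:
                quiet += 1
            rows.append(
                (tid, f, pos[0], pos[1], summed, bg_mean, bg_sd,
                 last["roi_label"], 0)
            )
            if quiet >= dead_frames:
                break
    out = tracks.copy()
    out["detected"] = 1
    if rows:
        extra = pd.DataFrame(rows, columns=TRACK_COLUMNS + ["detected"])
        out = pd.concat([out, extra], ignore_index=True)
    return out.sort_values(["track_id", "frame"]).reset_index(drop=True)


def track_stack(
    stack: ImageStack,
    mask: ROIMask | None,
    params: TrackingParams | None = None,
    extend_frames: int = 0,
    log: callable = None,
) -> pd.DataFrame:
    """Full per-stack pipeline: detect, measure, filter, link.

    ``extend_frames > 0`` additionally continues each track's intensity
    readout past its last detection (see :func:`extend_track_traces`).
    """
    params = params or TrackingParams()
    if mask is not None:
        mask.check_against(stack)
    spots_by_frame: list[list[Spot]] = []
    for f in range(stack.n_frames):
        spots = detect_spots(stack.pixels[f], mask, params, frame=f)
        spots = filter_candidates(spots, params)
        spots_by_frame.append(spots)
        if log is not None:
            log(f"frame {f}: {len(spots)} spots")
    tracks = link_tracks(spots_by_frame, params)
    if extend_frames > 0:
        tracks = extend_track_traces(stack, tracks, params, extend_frames)
    return tracks
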