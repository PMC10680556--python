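"""Single-molecule brightness calibration and stoichiometry estimation.

After sufficient photobleaching only step-like blinking remains at the
end of each track; the modal height of those terminal steps is the
characteristic single-molecule brightness.  Each track's initial
intensity — a linear backward extrapolation of its first four samples
to illumination onset — divided by that brightness gives the number of
tagged molecules (stoichiometry) in the complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde


class CalibrationError(RuntimeError):
    """Raised when too few terminal steps are available to calibrate."""


@dataclass
class BrightnessCalibration:
    brightness: float
    uncertainty: float
    n_steps: int
    step_heights: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if not self.brightness > 0:
            raise ValueError(f"brightness must be > 0; got {self.brightness}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def to_dict(self) -> dict:
        return {
            "brightness": float(self.brightness),
            "uncertainty": float(self.uncertainty),
            "n_steps": int(self.n_steps),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BrightnessCalibration":
        return cls(
            brightness=d["brightness"],
            uncertainty=d["uncertainty"],
            n_steps=d["n_steps"],
        )


@dataclass
class StoichiometrySample:
    track_id: int
    acquisition_id: int | str
    initial_intensity: float
    stoichiometry: float


def edge_preserving_filter(trace: np.ndarray, size: int = 3) -> np.ndarray:
    """Running-median filter: suppresses single-frame noise excursions
    without blurring step edges."""
    from scipy.signal import medfilt

    x = np.asarray(trace, dtype=float)
    if x.size < size:
        return x.copy()
    return medfilt(x, kernel_size=size if size % 2 else size + 1)


def _segment_plateaus(
    y: np.ndarray, min_size: int, sigma: float, significance: float
) -> list[tuple[int, int]]:
    """Binary segmentation of a trace into mean plateaus.

    Recursively splits at the change point with the largest mean shift;
    a split is accepted when the shift exceeds ``significance`` noise
    standard errors of the mean difference (so long plateaus resolve
    steps well below the per-frame noise).
    """
    segments: list[tuple[int, int]] = []

    def split(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * min_size:
            segments.append((lo, hi))
            return
        seg = y[lo:hi]
        best_k, best_score = -1, 0.0
        csum = np.cumsum(seg)
        total = csum[-1]
        for k in range(min_size, n - min_size + 1):
            left = csum[k - 1] / k
            right = (total - csum[k - 1]) / (n - k)
            se = max(sigma, 1e-12) * np.sqrt(1.0 / k + 1.0 / (n - k))
            score = abs(left - right) / se
            if score > best_score:
                best_score, best_k = score, k
        if best_k < 0 or best_score <= significance:
            segments.append((lo, hi))
            return
        split(lo, lo + best_k)
        split(lo + best_k, hi)

    split(0, y.size)
    return sorted(segments)


def terminal_step_heights(
    intensity_trace: np.ndarray,
    tail_fraction: float = 0.25,
    min_plateau: int = 2,
    filter_size: int = 3,
    significance: float = 4.0,
    boundary_trim: int = 1,
) -> list[float]:
    """Heights of the step-like blinking events at the end of a trace.

    The trailing low-intensity segment — the contiguous run of the
    edge-preserving (median) filtered trace below ``tail_fraction`` of
    the extrapolated initial intensity — is split into mean plateaus by
    noise-scaled binary segmentation of the raw samples; successive
    plateau-mean differences (absolute values) over plateaus of at
    least ``min_plateau`` frames are the step heights.  Plateau means
    exclude ``boundary_trim`` frame(s) at each boundary when the
    plateau is long enough (change points land within a frame of the
    true transition, so edge frames mix intensity levels).  A trace
    with no trailing segment gives an empty list.
    """
    trace = np.asarray(intensity_trace, dtype=float)
    if trace.size < 2:
        raise ValueError("trace must have length >= 2")
    if trace.size >= 4:
        i0 = initial_intensity(trace, 1.0)
    else:
        i0 = float(trace[0])
    threshold = tail_fraction * i0
    filtered = edge_preserving_filter(trace, filter_size)
    below = filtered < threshold
    if not below[-1]:
        return []
    # length of the trailing contiguous run below threshold
    run = 0
    for v in below[::-1]:
        if not v:
            break
        run += 1
    tail = trace[trace.size - run :]
    if tail.size < 2 * min_plateau:
        return []
    diffs = np.diff(tail)
    sigma = 1.4826 * np.median(np.abs(diffs - np.median(diffs))) / np.sqrt(2.0)
    segments = _segment_plateaus(tail, min_plateau, sigma, significance)
    means = []
    for lo, hi in segments:
        if hi - lo < min_plateau:
            continue
        if hi - lo >= min_plateau + 2 * boundary_trim:
            lo, hi = lo + boundary_trim, hi - boundary_trim
        means.append(float(tail[lo:hi].mean()))
    return [abs(means[i + 1] - means[i]) for i in range(len(means) - 1)]


def characteristic_brightness(
    step_heights: np.ndarray | list[float],
    min_steps: int = 20,
    grid_points: int = 4096,
) -> BrightnessCalibration:
    """Modal step height via a Gaussian KDE (Silverman bandwidth).

    The calibration value is the global mode of the density; the
    uncertainty is the half-width of the density's FWHM around it.
    """
    heights = np.asarray(step_heights, dtype=float)
    heights = heights[np.isfinite(heights) & (heights > 0)]
    if heights.size < min_steps:
        raise CalibrationError(
            f"only {heights.size} terminal steps available; need at least "
            f"{min_steps} — collect more acquisitions or lower the floor"
        )
    if np.ptp(heights) == 0:
        return BrightnessCalibration(
            brightness=float(heights[0]),
            uncertainty=0.0,
            n_steps=int(heights.size),
            step_heights=heights,
        )
    kde = gaussian_kde(heights, bw_method="silverman")
    bw = kde.factor * heights.std(ddof=1)
    grid = np.linspace(heights.min() - 3 * bw, heights.max() + 3 * bw, grid_points)
    density = kde(grid)
    imode = int(np.argmax(density))
    mode = float(grid[imode])
    half = density[imode] / 2.0
    above = density >= half
    lo = imode
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = imode
    while hi < grid.size - 1 and above[hi + 1]:
        hi += 1
    fwhm = float(grid[hi] - grid[lo])
    return BrightnessCalibration(
        brightness=mode,
        uncertainty=fwhm / 2.0,
        n_steps=int(heights.size),
        step_heights=heights,
    )


def initial_intensity(
    intensity_trace: np.ndarray, frame_interval: float, n_fit: int = 4
) -> float:
    """Backward linear extrapolation of the first ``n_fit`` samples.

    Ordinary least squares through the samples at frame-center times
    ``(i + 0.5) * frame_interval``, evaluated at ``t = 0`` (illumination
    onset).  Exact on affine traces; a constant trace returns its value.
    """
    trace = np.asarray(intensity_trace, dtype=float)
    if trace.size < n_fit:
        raise ValueError(f"trace length {trace.size} < {n_fit} frames required for extrapolation")
    t = (np.arange(n_fit) + 0.5) * frame_interval
    slope, intercept = np.polyfit(t, trace[:n_fit], 1)
    return float(intercept)


def stoichiometry(initial: float, calibration: BrightnessCalibration) -> float | None:
    """Fractional molecules per complex; ``None`` for non-physical samples."""
    value = initial / calibration.brightness
    return value if value > 0 else None


def calibrate_from_tracks(
    track_table: pd.DataFrame,
    min_steps: int = 20,
    per_acquisition: bool = False,
    max_start_frame: int | None = 1,
    **step_kwargs,
) -> BrightnessCalibration | dict:
    """Pool terminal steps across all tracks and calibrate.

    Only tracks present from the start of the acquisition (first frame
    at most ``max_start_frame``) contribute: late-starting fragments
    are dominated by re-detections and detection noise.  With
    ``per_acquisition=True`` (and an ``acquisition_id`` column) returns
    a dict of per-acquisition calibrations instead.
    """
    if per_acquisition and "acquisition_id" in track_table.columns:
        return {
            acq: calibrate_from_tracks(
                grp, min_steps=min_steps, max_start_frame=max_start_frame, **step_kwargs
            )
            for acq, grp in track_table.groupby("acquisition_id")
        }
    heights: list[float] = []
    for _, grp in track_table.groupby("track_id"):
        grp = grp.sort_values("frame")
        if max_start_frame is not None and int(grp["frame"].iloc[0]) > max_start_frame:
            continue
        trace = grp["summed_intensity"].to_numpy()
        if trace.size >= 4:
            heights.extend(terminal_step_heights(trace, **step_kwargs))
    return characteristic_brightness(heights, min_steps=min_steps)


def stoichiometries_from_tracks(
    track_table: pd.DataFrame,
    calibration: BrightnessCalibration,
    frame_interval: float,
    acquisition_id: int | str = 0,
    max_start_frame: int | None = 1,
    log: callable = None,
) -> pd.DataFrame:
    """One stoichiometry sample per track.

    Tracks shorter than 4 frames, or starting after ``max_start_frame``
    (extrapolation to illumination onset would be unreliable), or with
    non-positive stoichiometry are excluded with a logged reason.
    Columns: track_id, acquisition_id, initial_intensity, stoichiometry.
    """
    acq_col = "acquisition_id" in track_table.columns
    rows = []
    for tid, grp in track_table.groupby("track_id"):
        grp = grp.sort_values("frame")
        acq = grp["acquisition_id"].iloc[0] if acq_col else acquisition_id
        trace = grp["summed_intensity"].to_numpy()
        first = int(grp["frame"].iloc[0])
        if trace.size < 4:
            if log:
                log(f"track {tid}: excluded (length {trace.size} < 4)")
            continue
        if max_start_frame is not None and first > max_start_frame:
            if log:
                log(f"track {tid}: excluded (starts at frame {first})")
            continue
        init = initial_intensity(trace, frame_interval)
        stoich = stoichiometry(init, calibration)
        if stoich is None:
            if log:
                log(f"track {tid}: excluded (non-physical intensity {init:.1f})")
            continue
        rows.append((tid, acq, init, stoich))
    return pd.DataFrame(
        rows, columns=["track_id", "acquisition_id", "initial_intensity", "stoichiometry"]
    )
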