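"""Readers and writers for every on-disk artifact.

Conventions used throughout the package and documented in every file
header we emit:

* image axes are ``(frame, row, col)``, 0-based;
* centroids are sub-pixel floats in ``(row, col)`` order, where integer
  coordinates address pixel centers;
* frames are 0-based; times in seconds; intensities in photoelectrons.

Stacks are multipage 16-bit grayscale TIFF with a JSON metadata blob in
the image description.  Masks are single-page label TIFF/PNG (0 =
outside any ROI, ``k > 0`` = ROI ``k``).  Tabular artifacts are CSV with
a ``#``-prefixed schema line; results are JSON; configs are YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

TRACK_SCHEMA_VERSION = 1
STOICH_SCHEMA_VERSION = 1

TRACK_COLUMNS = [
    "track_id",
    "frame",
    "row",
    "col",
    "summed_intensity",
    "background_mean",
    "background_sd",
    "roi_label",
]

STOICH_COLUMNS = [
    "track_id",
    "acquisition_id",
    "initial_intensity",
    "stoichiometry",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its schema."""


@dataclass
class ImageStack:
    """Calibrated photoelectron-count movie.

    Parameters
    ----------
    pixels
        ``(frames, rows, cols)`` array of non-negative integer counts.
    pixel_size
        Pixel pitch in nm (paper optics: 53 nm/pixel).
    frame_interval
        Frame-to-frame period in seconds.
    exposure
        Exposure per frame in seconds.
    """

    pixels: np.ndarray
    pixel_size: float = 53.0
    frame_interval: float = 0.010
    exposure: float = 0.010

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise FormatError(
                f"stack must be (frames, rows, cols); got shape {self.pixels.shape}"
            )
        if np.issubdtype(self.pixels.dtype, np.signedinteger) and self.pixels.min() < 0:
            raise FormatError("photoelectron counts must be >= 0")
        if not self.frame_interval > 0:
            raise FormatError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]

    def frame_times(self) -> np.ndarray:
        """Frame-center timestamps ``(i + 0.5) * frame_interval`` in s."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_interval


@dataclass
class ROIMask:
    """Integer label image restricting analysis to acquisition ROIs."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError(f"mask must be 2-D; got shape {self.labels.shape}")
        self.labels = self.labels.astype(np.int32, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def check_against(self, stack: ImageStack) -> None:
        if self.shape != stack.shape:
            raise FormatError(
                f"mask shape {self.shape} does not match stack frames {stack.shape}"
            )


def write_stack(stack: ImageStack, path: str | Path) -> None:
    meta = {
        "pixel_size": stack.pixel_size,
        "frame_interval": stack.frame_interval,
        "exposure": stack.exposure,
        "axes": "(frame,row,col) 0-based",
    }
    tifffile.imwrite(
        path,
        np.asarray(stack.pixels, dtype=np.uint16),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    exposure: float | None = None,
) -> ImageStack:
    """Read a multipage TIFF stack.

    Metadata is taken from the JSON description written by
    :func:`write_stack`; explicit keyword overrides win.  Missing
    metadata without an override is an error.
    """
    with tifffile.TiffFile(path) as tif:
        pixels = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if pixels.ndim == 2:
        pixels = pixels[None]
    vals = {}
    for key, override in (
        ("pixel_size", pixel_size),
        ("frame_interval", frame_interval),
        ("exposure", exposure),
    ):
        if override is not None:
            vals[key] = override
        elif key in meta:
            vals[key] = float(meta[key])
        else:
            raise FormatError(f"stack metadata key '{key}' missing and no override given")
    return ImageStack(pixels=pixels, **vals)


def write_mask(mask: ROIMask, path: str | Path) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.uint16), photometric="minisblack")


def read_mask(path: str | Path) -> ROIMask:
    path = Path(path)
    if path.suffix.lower() == ".png":
        from imageio.v3 import imread

        labels = imread(path)
    else:
        labels = tifffile.imread(path)
    if labels.ndim == 3:  # RGB(A) PNG; labels live in one channel
        labels = labels[..., 0]
    return ROIMask(labels=labels)


def _validate_tracks(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"track table missing columns: {missing}")
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["track_id", "frame"]].tolist()
        raise FormatError(f"duplicate (track_id, frame) pair: {tuple(pair)}")
    for tid, grp in df.groupby("track_id"):
        frames = grp["frame"].to_numpy()
        if not np.all(np.diff(frames) > 0):
            raise FormatError(f"frames not strictly increasing within track {tid}")
    return df


def write_tracks(df: pd.DataFrame, path: str | Path) -> None:
    _validate_tracks(df)
    with open(path, "w") as fh:
        fh.write(
            f"# slimphys track table v{TRACK_SCHEMA_VERSION}; "
            "coords 0-based (row,col) pixel-center floats; frames 0-based\n"
        )
        df.to_csv(fh, index=False, columns=TRACK_COLUMNS)


def read_tracks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    df = df.sort_values(["track_id", "frame"]).reset_index(drop=True)
    return _validate_tracks(df)


def write_stoichiometries(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in STOICH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"stoichiometry table missing columns: {missing}")
    with open(path, "w") as fh:
        fh.write(
            f"# slimphys stoichiometry table v{STOICH_SCHEMA_VERSION}; "
            "intensities in photoelectrons; stoichiometry fractional\n"
        )
        df.to_csv(fh, index=False, columns=STOICH_COLUMNS)


def read_stoichiometries(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in STOICH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"stoichiometry table missing columns: {missing}")
    return df


def write_result(result: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(result, fh, indent=2, default=_default)
        fh.write("\n")


def read_result(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def load_config(path: str | Path, known_keys: set[str] | None = None) -> dict:
    """Load a YAML config, optionally rejecting unknown top-level keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config root must be a mapping; got {type(cfg).__name__}")
    if known_keys is not None:
        unknown = sorted(set(cfg) - known_keys)
        if unknown:
            raise FormatError(f"unknown config key(s): {', '.join(unknown)}")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
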