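"""Input/output for movies, channel images, cell masks and tabular results.

This module carries no analysis logic: it validates shapes and finiteness,
attaches acquisition metadata (frame rate, pixel size) and reads/writes the
plain formats the toolkit uses — multi-page TIFF for image stacks and CSV for
tables.  The frame rate is always a *user-supplied* argument and never read
from file metadata: the beat-frequency estimate scales linearly with fps, so
a silently wrong embedded value would corrupt every downstream number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, InputError

log = logging.getLogger(__name__)

# ITU-R BT.601 luma weights for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class Movie:
    """A time-ordered grayscale frame stack with known frame rate.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity values, time first.  At least two frames.
    fps : float
        Acquisition frame rate in frames per second; must be finite, > 0.
    pixel_size : float, optional
        Micrometres per pixel; purely informational, default 1.0.
    """

    frames: np.ndarray
    fps: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InputError(f"frames must be 3-D (T, H, W), got ndim={self.frames.ndim}")
        if self.frames.shape[0] < 2:
            raise InputError("a movie needs at least 2 frames")
        if not (np.isfinite(self.fps) and self.fps > 0):
            raise InputError(f"fps must be finite and positive, got {self.fps}")
        if not np.all(np.isfinite(self.frames)):
            raise InputError("movie intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        """Movie duration in seconds."""
        return self.n_frames / self.fps


@dataclass
class ChannelImage:
    """A single-channel 2-D fluorescence (or brightfield) image."""

    pixels: np.ndarray
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InputError("channel image must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("channel intensities must be finite")
        if np.any(self.pixels < 0):
            raise InputError("channel intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CellMaskImage:
    """Integer label image selecting cells: 0 = background, k > 0 = cell k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or labels.size == 0:
            raise InputError("cell mask must be a non-empty 2-D array")
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if not np.allclose(labels, rounded):
                raise InputError("cell mask labels must be integers")
            labels = rounded.astype(np.int64)
        if labels.min() < 0:
            raise InputError("cell mask labels must be non-negative")
        self.labels = labels

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def cell_ids(self) -> np.ndarray:
        """Sorted array of non-zero cell labels present in the mask."""
        ids = np.unique(self.labels)
        return ids[ids > 0]


def _read_tiff_gray(path: Path) -> np.ndarray:
    """Read a TIFF, collapsing an RGB(A) sample axis with BT.601 luma.

    Whether the trailing axis holds colour samples is taken from the TIFF
    series metadata, never guessed from the array shape.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            arr = series.asarray()
            axes = series.axes
    except Exception as exc:  # noqa: BLE001 - report as format error
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if axes.endswith("S") and arr.shape[-1] in (3, 4):
        log.info("converting RGB frames from %s to grayscale (BT.601 luma)", path)
        arr = arr[..., :3].astype(float) @ _LUMA
    return np.asarray(arr, dtype=float)


def read_movie(path: str | Path, fps: float, pixel_size: float = 1.0) -> Movie:
    """Read a movie from a multi-page TIFF or a directory of single-page TIFFs.

    ``fps`` is mandatory and authoritative; any frame-rate hint embedded in
    the TIFF is ignored (a mismatch is logged).  RGB frames are converted to
    grayscale.  Directories are read in sorted filename order, which must
    encode acquisition order.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in (".tif", ".tiff"))
        if len(files) < 2:
            raise InputError(f"directory {p} holds {len(files)} TIFF files; need >= 2")
        frames = []
        for f in files:
            page = _read_tiff_gray(f)
            if page.ndim != 2:
                raise FormatError(f"{f} is not a single 2-D frame (shape {page.shape})")
            frames.append(page)
        shapes = {fr.shape for fr in frames}
        if len(shapes) != 1:
            raise InputError(f"frames differ in shape: {sorted(shapes)}")
        stack = np.stack(frames)
    else:
        arr = _read_tiff_gray(p)
        if arr.ndim == 2:
            raise InputError(f"{p} holds a single frame; a movie needs >= 2")
        if arr.ndim != 3:
            raise FormatError(f"unsupported TIFF layout with shape {arr.shape}")
        stack = arr
    return Movie(stack, fps=fps, pixel_size=pixel_size)


def write_movie(movie: Movie, path: str | Path) -> None:
    """Write a movie as a multi-page float32 TIFF (one page per frame)."""
    tifffile.imwrite(
        Path(path),
        np.asarray(movie.frames, dtype=np.float32),
        photometric="minisblack",
    )


def read_channels(path_red: str | Path, path_green: str | Path) -> tuple[ChannelImage, ChannelImage]:
    """Read a red/green channel pair from two single-channel 2-D TIFFs.

    Intensities are preserved without rescaling (a 16-bit image keeps its
    0–65535 values).  Multi-channel files are rejected: one file per channel
    keeps channel semantics explicit.
    """
    images = []
    for path, name in ((path_red, "red"), (path_green, "green")):
        try:
            arr = tifffile.imread(Path(path))
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
        if arr.ndim != 2:
            raise InputError(
                f"{path} is not single-channel 2-D (shape {arr.shape}); "
                "split multi-channel images into one file per channel"
            )
        images.append(ChannelImage(arr, channel_name=name))
    if images[0].shape != images[1].shape:
        raise InputError(
            f"channel shapes differ: red {images[0].shape} vs green {images[1].shape}"
        )
    return images[0], images[1]


def read_cell_mask(path: str | Path) -> CellMaskImage:
    """Read an integer label mask (0 = background, k > 0 = cell k) from TIFF."""
    try:
        arr = tifffile.imread(Path(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim != 2:
        raise InputError(f"cell mask must be 2-D, got shape {arr.shape}")
    return CellMaskImage(arr)


def write_table(records: list[dict], path: str | Path) -> None:
    """Write flat records to CSV: alphabetical columns, UTF-8, '.' decimals.

    An empty record list is an error — a header-only file would silently
    propagate an upstream failure.
    """
    if not records:
        raise InputError("cannot write a table from an empty record list")
    keys = set(records[0])
    for i, rec in enumerate(records):
        if set(rec) != keys:
            raise InputError(f"record {i} has keys {sorted(rec)} != {sorted(keys)}")
    df = pd.DataFrame.from_records(records)[sorted(keys)]
    df.to_csv(Path(path), index=False, encoding="utf-8")
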