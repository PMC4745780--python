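"""Image-sequence and table I/O.

Sequences are multi-page TIFFs or directories of lexicographically ordered
frame images; metric tables are CSV. All intensities are preserved without
rescaling on read; internal processing is floating point.

Coordinate convention: row-major, origin top-left, 0-based; x = column,
y = row everywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("organotrack")

__all__ = [
    "Channel",
    "ImageSequence",
    "MaskSequence",
    "read_sequence",
    "write_sequence",
    "write_metrics_table",
    "read_metrics_table",
]


class Channel(str, Enum):
    phase = "phase"
    fluor_green = "fluor_green"
    fluor_red = "fluor_red"


@dataclass
class ImageSequence:
    """Ordered frames of a single imaging channel.

    frame_interval defaults to 1.0 hour per frame (one image per well per
    hour); pixel_size of ``None`` means uncalibrated ("pixels").
    """

    frames: list[np.ndarray]
    channel: Channel = Channel.phase
    frame_interval: float = 1.0      # hours
    pixel_size: float | None = None  # physical units per pixel, None = pixels

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("ImageSequence requires at least one frame")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.ndim != 2:
                raise ValueError(f"frame {i} is not 2-D (shape {f.shape})")
            if f.shape != shape:
                raise ValueError(
                    f"frame {i} shape {f.shape} differs from frame 0 shape {shape}"
                )
            if not np.all(np.isfinite(np.asarray(f, dtype=float))):
                raise ValueError(f"frame {i} contains non-finite intensities")
        self.channel = Channel(self.channel)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def timestamps(self) -> np.ndarray:
        """Frame times in hours (index x frame_interval)."""
        return np.arange(self.n_frames) * self.frame_interval

    def __len__(self) -> int:
        return self.n_frames

    def map(self, fn) -> "ImageSequence":
        """Apply ``fn`` per frame, keeping metadata."""
        return ImageSequence([fn(f) for f in self.frames], self.channel,
                             self.frame_interval, self.pixel_size)


@dataclass
class MaskSequence:
    """Binary masks aligned to an ImageSequence (values in {0, 1})."""

    frames: list[np.ndarray]
    source_channel: Channel = Channel.fluor_green
    aligned_to: str = ""

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("MaskSequence requires at least one frame")
        shape = self.frames[0].shape
        norm = []
        for i, f in enumerate(self.frames):
            if f.shape != shape:
                raise ValueError(f"mask {i} shape {f.shape} differs from {shape}")
            m = np.asarray(f)
            if m.dtype != bool:
                vals = np.unique(m)
                if not np.all(np.isin(vals, (0, 1))):
                    raise ValueError(f"mask {i} has values outside {{0,1}}")
                m = m.astype(bool)
            norm.append(m)
        self.frames = norm
        self.source_channel = Channel(self.source_channel)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return self.n_frames


_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


def read_sequence(path: str | Path, channel: Channel | str = Channel.phase,
                  frame_interval: float = 1.0) -> ImageSequence:
    """Read a multi-page TIFF or a directory of frame images, in order.

    Directory frames are sorted lexicographically by file name. Intensities
    are preserved without rescaling.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise IOError(f"no frame images found in directory {path}")
        frames = [tifffile.imread(str(p)) if p.suffix.lower() in (".tif", ".tiff")
                  else _read_png(p) for p in files]
    elif path.is_file():
        arr = tifffile.imread(str(path))
        if arr.ndim == 2:
            frames = [arr]
        elif arr.ndim == 3:
            frames = [arr[i] for i in range(arr.shape[0])]
        else:
            raise ValueError(f"unsupported TIFF dimensionality {arr.ndim} in {path}")
    else:
        raise IOError(f"no such file or directory: {path}")

    shape = frames[0].shape
    for i, f in enumerate(frames):
        if f.shape != shape:
            raise ValueError(
                f"frame {i} in {path} has shape {f.shape}, expected {shape}")
    return ImageSequence(frames, Channel(channel), frame_interval)


def _read_png(p: Path) -> np.ndarray:
    import imageio.v3 as iio
    a = iio.imread(p)
    if a.ndim == 3:  # collapse trivially replicated channels
        a = a[..., 0]
    return a


def write_sequence(seq: ImageSequence | MaskSequence, path: str | Path) -> None:
    """Write a sequence as a multi-page TIFF, preserving dtype (masks as uint8)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = seq.frames
    if isinstance(seq, MaskSequence) or frames[0].dtype == bool:
        stack = np.stack([f.astype(np.uint8) for f in frames])
    else:
        stack = np.stack(frames)
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def write_metrics_table(records, path: str | Path) -> None:
    """Write tabular metrics as CSV with a header row, full numeric precision.

    ``records`` may be a DataFrame or a non-empty list of dicts with
    homogeneous keys.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records:
            raise ValueError("refusing to write an empty metrics table")
        cols = list(records[0].keys())
        for i, r in enumerate(records):
            if list(r.keys()) != cols:
                raise ValueError(f"record {i} columns differ from record 0")
        df = pd.DataFrame.from_records(records)
    if df.empty:
        raise ValueError("refusing to write an empty metrics table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_overlay_png(rgb: np.ndarray, path: str | Path) -> None:
    """Write an RGB uint8 QC overlay as PNG."""
    import imageio.v3 as iio
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(rgb, dtype=np.uint8))


def setup_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(level=level,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
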