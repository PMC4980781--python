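"""Reading, writing and validating frame sequences and label masks.

All pixel data is promoted to ``float64`` immediately after decoding; the
PDE stages downstream require fractional intensities.  Coordinates are
0-based ``(row, col)``, row-major, with pixel centers at integer positions.

Supported on-disk formats are 8/16-bit grayscale TIFF (single- and
multi-page) and PNG for frames, and 16-bit TIFF for integer label masks
(Cell Tracking Challenge ``man_seg{TTT}.tif`` style naming by default).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "ImageFrame",
    "FrameSequence",
    "FrameTriplet",
    "LabelMask",
    "read_sequence",
    "read_labels",
    "write_labels",
]

_FRAME_SUFFIXES = {".tif", ".tiff", ".png"}


@dataclass(frozen=True)
class ImageFrame:
    """One 2D grayscale frame.

    Parameters
    ----------
    pixels : ndarray
        2D array of nonnegative finite intensities (arbitrary units).
        Stored as float64.
    bit_depth : int
        Source bit depth, 8 or 16.
    frame_index : int
        0-based time index within the sequence.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2:
            raise ValueError(f"frame must be 2D grayscale, got shape {px.shape}")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError(
                "frame too small: the diffusion stencil requires height and "
                f"width >= 3, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("frame contains non-finite intensities")
        if px.min() < 0:
            raise ValueError("frame contains negative intensities")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class FrameSequence:
    """A time-ordered sequence of shape-consistent frames."""

    frames: tuple[ImageFrame, ...]
    global_min: float = field(init=False)
    global_max: float = field(init=False)

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        object.__setattr__(self, "frames", frames)
        if not frames:
            raise ValueError("sequence contains zero frames")
        shape = frames[0].shape
        for f in frames:
            if f.shape != shape:
                raise ValueError(
                    f"inconsistent frame shapes: {shape} vs {f.shape}"
                )
        gmin = min(float(f.pixels.min()) for f in frames)
        gmax = max(float(f.pixels.max()) for f in frames)
        if not gmax > gmin:
            raise ValueError("degenerate sequence: global_max must exceed global_min")
        object.__setattr__(self, "global_min", gmin)
        object.__setattr__(self, "global_max", gmax)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> ImageFrame:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def triplet(self, t: int) -> "FrameTriplet":
        """Three-frame window ``{t-1, t, t+1}`` with replicate temporal padding.

        At the sequence boundaries the missing neighbor is the center frame
        itself (zero temporal gradient), and the corresponding padded flag
        is set.
        """
        if not 0 <= t < len(self.frames):
            raise IndexError(f"frame index {t} out of range")
        padded_prev = t == 0
        padded_next = t == len(self.frames) - 1
        prev = self.frames[t if padded_prev else t - 1]
        nxt = self.frames[t if padded_next else t + 1]
        return FrameTriplet(
            prev=prev,
            center=self.frames[t],
            next=nxt,
            padded_prev=padded_prev,
            padded_next=padded_next,
        )


@dataclass(frozen=True)
class FrameTriplet:
    """Three consecutive frames ``{t-1, t, t+1}``; the diffusion solver unit."""

    prev: ImageFrame
    center: ImageFrame
    next: ImageFrame
    padded_prev: bool = False
    padded_next: bool = False

    def __post_init__(self) -> None:
        if not (self.prev.shape == self.center.shape == self.next.shape):
            raise ValueError("triplet frames must share a single shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.center.shape

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.prev.pixels, self.center.pixels, self.next.pixels


@dataclass(frozen=True)
class LabelMask:
    """Integer instance labels for one frame: 0 = background, k > 0 = cell k."""

    labels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("label mask must be 2D")
        if not np.issubdtype(lab.dtype, np.integer):
            if np.any(lab != np.round(lab)):
                raise ValueError("label mask must contain integers")
            lab = lab.astype(np.int64)
        if lab.min() < 0:
            raise ValueError("label mask contains negative labels")
        object.__setattr__(self, "labels", lab)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def binary(self) -> np.ndarray:
        return self.labels > 0

    @property
    def n_instances(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))


def _natural_key(path: Path):
    """Sort key ordering embedded integers numerically (frame_2 < frame_10)."""
    parts = re.split(r"(\d+)", path.name)
    return [int(p) if p.isdigit() else p for p in parts]


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    return 16


def _decode_gray(arr: np.ndarray, source: str) -> np.ndarray:
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValueError(f"non-grayscale or non-2D input: {source} ({arr.shape})")
    return arr


def _read_one(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def read_sequence(path: str | Path, pattern: str = "*") -> FrameSequence:
    """Read a frame sequence from a multi-page TIFF or a directory.

    Parameters
    ----------
    path : str or Path
        A multi-page TIFF file, or a directory containing numbered
        single-frame TIFF/PNG files.
    pattern : str
        Glob pattern selecting files within a directory; frames are ordered
        by natural (numeric-aware) name order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such path: {path}")

    arrays: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(
            (p for p in path.glob(pattern)
             if p.suffix.lower() in _FRAME_SUFFIXES),
            key=_natural_key,
        )
        if not files:
            raise FileNotFoundError(f"zero frames found in {path} (pattern {pattern!r})")
        for p in files:
            arr = _read_one(p)
            if arr.ndim == 3 and p.suffix.lower() in {".tif", ".tiff"}:
                # a multi-page tiff inside a directory contributes all pages
                arrays.extend(_decode_gray(a, str(p)) for a in arr)
            else:
                arrays.append(_decode_gray(arr, str(p)))
    else:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arrays = [arr]
        elif arr.ndim == 3:
            arrays = [_decode_gray(a, str(path)) for a in arr]
        else:
            raise ValueError(f"non-grayscale input: {path} ({arr.shape})")

    frames = [
        ImageFrame(pixels=a, bit_depth=_bit_depth_of(np.asarray(a)), frame_index=i)
        for i, a in enumerate(arrays)
    ]
    return FrameSequence(frames=tuple(frames))


def write_labels(
    masks: Sequence[LabelMask],
    path: str | Path,
    prefix: str = "man_seg",
    digits: int = 3,
) -> list[Path]:
    """Write instance label masks as 16-bit TIFFs, one per frame.

    Files are named ``{prefix}{TTT}.tif`` with zero-padded frame numbers.
    Rereading with :func:`read_labels` reproduces labels bit-exactly.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("empty mask list")
    shape = masks[0].shape
    for m in masks:
        if m.shape != shape:
            raise ValueError("inconsistent mask shapes")
        if m.labels.max(initial=0) > np.iinfo(np.uint16).max:
            raise ValueError("label exceeds 16-bit range")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for i, m in enumerate(masks):
        out = path / f"{prefix}{i:0{digits}d}.tif"
        tifffile.imwrite(out, m.labels.astype(np.uint16))
        written.append(out)
    return written


def read_labels(path: str | Path, pattern: str = "*.tif*") -> list[LabelMask]:
    """Read a directory of label-mask TIFFs in natural name order."""
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"no such directory: {path}")
    files = sorted(path.glob(pattern), key=_natural_key)
    if not files:
        raise FileNotFoundError(f"zero masks found in {path}")
    return [
        LabelMask(labels=tifffile.imread(p).astype(np.int64), frame_index=i)
        for i, p in enumerate(files)
    ]
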