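"""Frame containers and image loading.

A :class:`Frame` is a 2-D grayscale intensity grid with a timestamp; a
:class:`FrameSequence` is an ordered, uniformly spaced list of frames — the
raw observable of the assay (one image per second per well in the original
setup).  Color images are converted to grayscale with the Rec. 601 luma
weights before any processing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["Frame", "FrameSequence", "to_grayscale", "load_sequence"]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg")

# Rec. 601 luma weights for RGB -> intensity
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3|4) color image to (H, W) intensity; pass 2-D through."""
    if pixels.ndim == 2:
        return pixels
    if pixels.ndim == 3 and pixels.shape[2] in (3, 4):
        return pixels[..., :3].astype(np.float64) @ _LUMA
    raise ValueError(f"cannot interpret array of shape {pixels.shape} as an image")


@dataclass(frozen=True)
class Frame:
    """One grayscale image with its acquisition time in seconds."""

    pixels: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        px = to_grayscale(np.asarray(self.pixels))
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError("frames must be at least 3x3 pixels")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class FrameSequence:
    """Uniformly sampled ordered frames of one well / one animal."""

    frames: list[Frame]
    capture_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.capture_interval <= 0:
            raise ValueError("capture_interval must be positive")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames have mixed shapes: {sorted(shapes)}")
        ts = [f.timestamp for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("frame timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @classmethod
    def from_arrays(cls, arrays: Sequence[np.ndarray],
                    capture_interval: float = 1.0,
                    t0: float = 0.0) -> "FrameSequence":
        frames = [Frame(a, t0 + i * capture_interval) for i, a in enumerate(arrays)]
        return cls(frames=frames, capture_interval=capture_interval)


def load_sequence(source: str | Path, capture_interval: float = 1.0) -> FrameSequence:
    """Load a sequence from a directory of images or a manifest CSV.

    A directory is read in lexicographic filename order (capture tools number
    their output, so name order is time order).  A manifest CSV must have
    columns ``frame_path, timestamp_s``; paths are resolved relative to the
    manifest's directory.
    """
    import imageio.v3 as iio

    source = Path(source)
    if source.is_dir():
        paths = sorted(p for p in source.iterdir()
                       if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not paths:
            raise FileNotFoundError(f"no image files found in {source}")
        frames = [Frame(iio.imread(p), i * capture_interval)
                  for i, p in enumerate(paths)]
        return FrameSequence(frames=frames, capture_interval=capture_interval)

    if source.suffix.lower() == ".csv":
        frames = []
        with open(source) as fh:
            for row in csv.DictReader(fh):
                p = Path(row["frame_path"])
                if not p.is_absolute():
                    p = source.parent / p
                frames.append(Frame(iio.imread(p), float(row["timestamp_s"])))
        if not frames:
            raise FileNotFoundError(f"manifest {source} lists no frames")
        ts = [f.timestamp for f in frames]
        dt = ts[1] - ts[0] if len(ts) > 1 else capture_interval
        return FrameSequence(frames=frames, capture_interval=dt)

    raise FileNotFoundError(f"{source} is neither a directory nor a manifest CSV")
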