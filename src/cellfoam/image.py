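"""Image carriers: single frames and time-lapse stacks with physical metadata.

Coordinate convention, used everywhere in this package: 0-based pixel
indices, ``(x = column, y = row)``, pixel centers at integer coordinates.
Angles are measured from the +x axis, counter-clockwise in image
coordinates (i.e. toward -y on screen).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import tifffile


@dataclass(frozen=True)
class ImageFrame:
    """A 2D intensity grid with pixel size (μm/px) and a timestamp (s)."""

    data: np.ndarray
    pixel_size: float = 1.0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.size == 0:
            raise ValueError("ImageFrame requires a non-empty 2D grid")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "ImageFrame":
        return ImageFrame(data, pixel_size=self.pixel_size, timestamp=self.timestamp)


@dataclass
class TimeLapse:
    """An ordered sequence of frames sharing one pixel size.

    ``times`` carries per-frame timestamps in seconds; they need not be
    evenly spaced (e.g. around an ablation gap).
    """

    frames: np.ndarray  # (n_frames, rows, cols)
    pixel_size: float = 1.0
    times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.size == 0:
            raise ValueError("TimeLapse requires a non-empty (t, y, x) array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        times = np.asarray(self.times, dtype=float)
        if times.size == 0:
            times = np.arange(len(self.frames), dtype=float)
        if times.shape != (len(self.frames),):
            raise ValueError("times must have one entry per frame")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.times = times

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> ImageFrame:
        return ImageFrame(self.frames[i], pixel_size=self.pixel_size,
                          timestamp=float(self.times[i]))

    def __iter__(self) -> Iterator[ImageFrame]:
        for i in range(len(self)):
            yield self[i]

    def subset(self, indices: Sequence[int]) -> "TimeLapse":
        idx = np.asarray(indices, dtype=int)
        return TimeLapse(self.frames[idx], pixel_size=self.pixel_size,
                         times=self.times[idx])


def read_stack(path: str | Path, pixel_size: float = 1.0,
               frame_interval: float = 1.0) -> TimeLapse:
    """Read a single-channel multi-page TIFF as a :class:`TimeLapse`.

    Pixel size (μm/px) and frame interval (s) are supplied by the caller;
    sidecar metadata parsing is the CLI's job.
    """
    arr = tifffile.imread(str(path))
    if arr.size == 0:
        raise ValueError(f"empty stack: {path}")
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a single-channel stack, got shape {arr.shape}")
    times = np.arange(len(arr)) * float(frame_interval)
    return TimeLapse(arr, pixel_size=pixel_size, times=times)


def write_stack(path: str | Path, stack: TimeLapse | np.ndarray) -> None:
    arr = stack.frames if isinstance(stack, TimeLapse) else np.asarray(stack)
    tifffile.imwrite(str(path), np.asarray(arr, dtype=np.float32))
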