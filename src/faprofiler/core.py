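"""Shared containers: the projected two-channel image and the axis pixel chain.

Distances along an axis chain follow the pixel-step geometry used throughout
the analysis: at 40 nm pixel pitch a straight (4-connected) step covers 40 nm
and a diagonal step covers sqrt(40^2 + 40^2) = sqrt(3200) ~ 56.6 nm.  Other
pitches scale both step lengths proportionally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

RED = "red"
GREEN = "green"
NONE = "none"


@dataclass
class ProjectedImagePair:
    """Aligned red/green 2D intensity grids with physical pixel pitch."""

    red: np.ndarray
    green: np.ndarray
    pixel_pitch_nm: float = 40.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if self.red.shape != self.green.shape:
            raise ValueError("red and green grids must have the same shape")
        if self.red.ndim != 2:
            raise ValueError("channel grids must be 2D")
        if self.pixel_pitch_nm <= 0:
            raise ValueError("pixel_pitch_nm must be positive")
        if self.red.min() < 0 or self.green.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    def channel(self, role: str) -> np.ndarray:
        if role == RED:
            return self.red
        if role == GREEN:
            return self.green
        raise KeyError(role)

    def swapped(self) -> "ProjectedImagePair":
        """Return a copy with the red and green roles exchanged."""
        return ProjectedImagePair(
            self.green.copy(), self.red.copy(), self.pixel_pitch_nm,
            dict(self.provenance, channel_swap=True),
        )


@dataclass
class AxisPath:
    """Ordered 8-connected pixel chain along an FA long axis.

    Index 0 is the head (distal) end once the path has been oriented.
    Each step between consecutive pixels is either straight (one of row or
    col changes) or diagonal (both change); cumulative physical distance is
    the sum of per-step lengths.
    """

    pixels: np.ndarray  # (n, 2) int array of (row, col)
    pixel_pitch_nm: float = 40.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValueError("pixels must be an (n, 2) array")
        if len(self.pixels) >= 2:
            d = np.abs(np.diff(self.pixels, axis=0))
            if d.max() > 1 or (d.sum(axis=1) == 0).any():
                raise ValueError("consecutive path pixels must be 8-adjacent and distinct")

    def __len__(self) -> int:
        return len(self.pixels)

    @property
    def diagonal_steps(self) -> np.ndarray:
        """Boolean flag per step: True where both row and col change."""
        d = np.abs(np.diff(self.pixels, axis=0))
        return (d[:, 0] == 1) & (d[:, 1] == 1)

    @property
    def step_lengths_nm(self) -> np.ndarray:
        p = self.pixel_pitch_nm
        return np.where(self.diagonal_steps, p * math.sqrt(2.0), p)

    @property
    def cumulative_nm(self) -> np.ndarray:
        """Distance from the head pixel to each pixel, in nm."""
        return np.concatenate([[0.0], np.cumsum(self.step_lengths_nm)])

    def length_nm(self, i0: int = 0, i1: int | None = None) -> float:
        """Path distance between pixel indices ``i0`` and ``i1`` (inclusive ends)."""
        if i1 is None:
            i1 = len(self.pixels) - 1
        cum = self.cumulative_nm
        return float(abs(cum[i1] - cum[i0]))

    def reversed(self) -> "AxisPath":
        return AxisPath(self.pixels[::-1].copy(), self.pixel_pitch_nm)


def path_length_nm(path: AxisPath | Sequence, i0: int = 0, i1: int | None = None,
                   pixel_pitch_nm: float = 40.0) -> float:
    """Physical length of a (sub-)chain under the straight/diagonal step rule.

    ``path`` may be an :class:`AxisPath` or a raw (n, 2) pixel sequence; an
    empty or single-pixel segment has length 0.
    """
    if not isinstance(path, AxisPath):
        arr = np.asarray(path, dtype=int).reshape(-1, 2)
        if len(arr) < 2:
            return 0.0
        path = AxisPath(arr, pixel_pitch_nm)
    if len(path) < 2:
        return 0.0
    return path.length_nm(i0, i1)


def rasterize_segment(p0: Sequence[float], p1: Sequence[float]) -> np.ndarray:
    """8-connected Bresenham chain of integer pixels from ``p0`` to ``p1``.

    End points are rounded to the nearest pixel; the chain includes both.
    """
    from skimage.draw import line

    r0, c0 = int(round(p0[0])), int(round(p0[1]))
    r1, c1 = int(round(p1[0])), int(round(p1[1]))
    rr, cc = line(r0, c0, r1, c1)
    return np.column_stack([rr, cc])
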