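"""Gridded 2-D image containers with world (mm) geometry.

Pixel (i, j) sits at world position ``origin + (i, j) * spacing`` (pixel
centers, 0-based indices).  All world coordinates are millimetres.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GridMismatchError


def _as_pair(v) -> np.ndarray:
    a = np.broadcast_to(np.asarray(v, dtype=float), (2,)).copy()
    return a


@dataclass
class GrayscaleImage:
    """2-D intensity image with per-axis pixel spacing and world origin."""

    pixels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(2))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        self.spacing = _as_pair(self.spacing)
        self.origin = _as_pair(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class BinaryMask:
    """Boolean pixel set sharing the GrayscaleImage geometry convention."""

    pixels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(2))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        self.spacing = _as_pair(self.spacing)
        self.origin = _as_pair(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def shape(self):
        return self.pixels.shape

    @property
    def count(self) -> int:
        return int(self.pixels.sum())

    def is_empty(self) -> bool:
        return not self.pixels.any()

    def world_coords(self) -> np.ndarray:
        """(K, 2) world coordinates (mm) of member-pixel centers."""
        idx = np.argwhere(self.pixels)
        return self.origin[None, :] + idx * self.spacing[None, :]

    def same_geometry(self, other: "BinaryMask", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def require_same_geometry(self, other: "BinaryMask") -> None:
        if not self.same_geometry(other):
            raise GridMismatchError("masks do not share grid geometry")


def world_grid(mask_or_image) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis world coordinates (mm) of pixel centers."""
    n0, n1 = mask_or_image.shape
    sp, o = mask_or_image.spacing, mask_or_image.origin
    return o[0] + np.arange(n0) * sp[0], o[1] + np.arange(n1) * sp[1]
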