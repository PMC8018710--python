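"""Treatment-path planning: waypoint interpolation and hexagonal packing.

A vessel treatment path is a piecewise-linear chain through user waypoints,
re-parameterized by arc length and sampled at fixed increments (0.5 mm by
default, matching the insonation step).  An areal treatment is a triangular
(hexagonally packed) lattice of focus stops at fixed pitch clipped to a
drawn region of interest.  Plans carry pulse bookkeeping (pulses per stop,
frame decimation) as metadata only; no hardware control.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .images import BinaryMask

__all__ = [
    "Waypoint",
    "InsonationPlan",
    "RegionOfInterest",
    "interpolate_path",
    "hex_pack",
    "tracking_error_series",
]

#: clot-protocol pulse bookkeeping: 500 pulses/stop at 40 Hz, every 10th imaged
CLOT_PULSES_PER_STOP = 500
FRAME_DECIMATION = 10
PULSE_RATE_HZ = 40.0
#: phantom protocol: 200 single-cycle pulses per stop
PHANTOM_PULSES_PER_STOP = 200


@dataclass
class Waypoint:
    position: np.ndarray       # (3,) mm, world frame
    label: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("waypoint position must be (x, y, z) in mm")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("waypoint coordinates must be finite")


@dataclass
class InsonationPlan:
    """Ordered focus stops (mm) with per-stop pulse bookkeeping."""

    stops: np.ndarray                 # (M, 3) mm
    step: float                       # mm arc-length increment
    pulses_per_stop: int = CLOT_PULSES_PER_STOP
    frame_decimation: int = FRAME_DECIMATION

    def __post_init__(self):
        self.stops = np.atleast_2d(np.asarray(self.stops, dtype=float))
        if self.stops.shape[1] != 3:
            raise ValueError("stops must be (M, 3)")

    @property
    def n_stops(self) -> int:
        return self.stops.shape[0]

    @property
    def frames_per_stop(self) -> int:
        """Passive frames recorded per stop (one frame per N-th pulse)."""
        return self.pulses_per_stop // self.frame_decimation

    @property
    def total_frames(self) -> int:
        return self.n_stops * self.frames_per_stop


def _as_positions(waypoints) -> np.ndarray:
    rows = []
    for w in waypoints:
        rows.append(w.position if isinstance(w, Waypoint) else np.asarray(w, float))
    pos = np.atleast_2d(np.array(rows, dtype=float))
    if pos.shape[1] == 2:
        pos = np.column_stack([pos, np.zeros(pos.shape[0])])
    if pos.shape[1] != 3:
        raise ValueError("waypoints must be 2-D or 3-D positions")
    return pos


def interpolate_path(
    waypoints: Sequence,
    step: float = 0.5,
    pulses_per_stop: int = CLOT_PULSES_PER_STOP,
    frame_decimation: int = FRAME_DECIMATION,
) -> InsonationPlan:
    """Arc-length resampling of the piecewise-linear waypoint chain.

    Stops sit at s = 0, step, 2 step, ... along the chain; the final
    waypoint is always included as a stop (so the treated extent equals the
    planned extent) even when its spacing from the previous stop is short.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    pos = _as_positions(waypoints)
    keep = [0]
    for i in range(1, pos.shape[0]):
        if np.linalg.norm(pos[i] - pos[keep[-1]]) < 1e-9:
            warnings.warn("duplicate consecutive waypoint collapsed", stacklevel=2)
        else:
            keep.append(i)
    pos = pos[keep]
    if pos.shape[0] == 1:
        return InsonationPlan(pos.copy(), step, pulses_per_stop, frame_decimation)
    seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    L = cum[-1]
    n_whole = int(np.floor(L / step + 1e-9))
    s = np.arange(n_whole + 1) * step
    if L - s[-1] > 1e-3:       # include the terminal waypoint (tolerance 1 um)
        s = np.append(s, L)
    else:
        s[-1] = L if abs(L - s[-1]) <= 1e-3 else s[-1]
    stops = np.column_stack([np.interp(s, cum, pos[:, d]) for d in range(3)])
    return InsonationPlan(stops, step, pulses_per_stop, frame_decimation)


@dataclass
class RegionOfInterest:
    """Planar region in image-plane mm coordinates: polygon or pixel mask."""

    polygon: Optional[Polygon] = None
    mask: Optional[BinaryMask] = None

    def __post_init__(self):
        if (self.polygon is None) == (self.mask is None):
            raise ValueError("provide exactly one of polygon or mask")
        if self.polygon is not None:
            if self.polygon.is_empty or not self.polygon.is_valid:
                raise ValueError("polygon must be a non-empty simple polygon")
        elif self.mask.is_empty():
            raise ValueError("ROI mask is empty")

    @classmethod
    def from_polygon(cls, coords) -> "RegionOfInterest":
        return cls(polygon=Polygon(coords))

    @classmethod
    def from_mask(cls, mask: BinaryMask) -> "RegionOfInterest":
        return cls(mask=mask)

    def centroid(self) -> np.ndarray:
        if self.polygon is not None:
            c = self.polygon.centroid
            return np.array([c.x, c.y])
        return self.mask.world_coords().mean(axis=0)

    def bounds(self):
        if self.polygon is not None:
            return self.polygon.bounds
        wc = self.mask.world_coords()
        return wc[:, 0].min(), wc[:, 1].min(), wc[:, 0].max(), wc[:, 1].max()

    def covers(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        if self.polygon is not None:
            import shapely

            return shapely.covers(self.polygon, shapely.points(pts))
        idx = np.round(
            (pts - self.mask.origin[None, :]) / self.mask.spacing[None, :]
        ).astype(int)
        ok = (
            (idx[:, 0] >= 0) & (idx[:, 0] < self.mask.shape[0])
            & (idx[:, 1] >= 0) & (idx[:, 1] < self.mask.shape[1])
        )
        out = np.zeros(pts.shape[0], dtype=bool)
        out[ok] = self.mask.pixels[idx[ok, 0], idx[ok, 1]]
        return out


def hex_pack(roi: RegionOfInterest, pitch: float = 0.5) -> np.ndarray:
    """Hexagonally packed focus stops at fixed pitch clipped to the ROI.

    Triangular lattice: rows pitch*sqrt(3)/2 apart, alternate rows shifted by
    pitch/2, anchored at the ROI centroid with rows parallel to the first
    (azimuth) axis.  An ROI smaller than one lattice cell yields the single
    centroid point (explicit policy).
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    cx, cy = roi.centroid()
    x0, y0, x1, y1 = roi.bounds()
    row_h = pitch * np.sqrt(3) / 2
    j_min = int(np.floor((y0 - cy) / row_h)) - 1
    j_max = int(np.ceil((y1 - cy) / row_h)) + 1
    pts = []
    for j in range(j_min, j_max + 1):
        y = cy + j * row_h
        off = (pitch / 2) if (j % 2) else 0.0
        i_min = int(np.floor((x0 - cx - off) / pitch)) - 1
        i_max = int(np.ceil((x1 - cx - off) / pitch)) + 1
        xs = cx + off + np.arange(i_min, i_max + 1) * pitch
        pts.append(np.column_stack([xs, np.full(xs.size, y)]))
    lattice = np.vstack(pts)
    inside = roi.covers(lattice)
    if not inside.any():
        return np.array([[cx, cy]])
    return lattice[inside]


def tracking_error_series(
    plan: InsonationPlan, measured_centroids: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Per-stop Euclidean distance between planned focus and measured
    centroid, with the mean +/- SD summary.  Centroids may be 2-D (in-plane)
    or 3-D; 2-D centroids are compared against the matching stop coordinates.
    """
    cent = np.atleast_2d(np.asarray(measured_centroids, dtype=float))
    if cent.shape[0] != plan.n_stops:
        raise ValueError("one measured centroid required per stop")
    k = cent.shape[1]
    if k not in (2, 3):
        raise ValueError("centroids must be 2-D or 3-D")
    err = np.linalg.norm(plan.stops[:, :k] - cent, axis=1)
    return err, float(err.mean()), float(err.std(ddof=0))
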