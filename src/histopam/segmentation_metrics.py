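"""Segmentation, co-registration, and ablation-accuracy metrics.

Regions (lumen, clot, emission area, predicted and actual liquefaction) are
binary pixel sets in world millimetres.  Accuracy is quantified by the
distance between the therapy focus and a region centroid, the Dice
similarity coefficient

    DSC = 2 |A ∩ B| / (|A| + |B|)

and the directed Hausdorff distance

    h(A, B) = max_{a in A} min_{b in B} d(a, b)

over member-pixel centers with Euclidean d.  Planning and post-treatment
frames are co-registered by a least-squares rigid (optionally similarity)
transform fit to matched fiducial pairs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import binary_fill_holes
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label

from .exceptions import DegenerateHistogramError, GridMismatchError, UndefinedCentroidError
from .images import BinaryMask, GrayscaleImage

__all__ = [
    "RigidTransform2D",
    "TargetingRecord",
    "otsu_mask",
    "component_centroid",
    "dice",
    "hausdorff",
    "register_fiducials",
    "transform_mask",
    "targeting_error",
    "segment_clot",
]


def _remove_specks(raw: np.ndarray, min_size: int) -> np.ndarray:
    """Drop connected components below min_size pixels."""
    lab, n = label(raw, return_num=True)
    if n == 0:
        return raw
    counts = np.bincount(lab.ravel())
    keep = np.flatnonzero(counts >= min_size)
    keep = keep[keep != 0]
    return np.isin(lab, keep)


def otsu_mask(
    image: GrayscaleImage,
    polarity: str = "dark",
    min_size: int = 5,
    largest_only: bool = True,
    fill_holes: bool = True,
) -> BinaryMask:
    """Otsu threshold (maximum between-class variance) + morphological cleanup.

    ``polarity`` keeps the class above ("bright") or below ("dark") the
    threshold; specks under ``min_size`` pixels are removed, holes filled,
    and by default only the largest connected component is retained.
    """
    if polarity not in ("bright", "dark"):
        raise ValueError("polarity must be 'bright' or 'dark'")
    px = image.pixels
    if np.ptp(px) == 0:
        raise DegenerateHistogramError("constant image has no Otsu threshold")
    thr = threshold_otsu(px)
    raw = px > thr if polarity == "bright" else px <= thr
    if min_size > 1:
        raw = _remove_specks(raw, min_size)
    if fill_holes:
        raw = binary_fill_holes(raw)
    if largest_only and raw.any():
        lab = label(raw)
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        raw = lab == counts.argmax()
    return BinaryMask(raw, image.spacing, image.origin)


def segment_clot(image: GrayscaleImage, lumen: BinaryMask) -> BinaryMask:
    """Segment the clot as the brighter Otsu class *within* the lumen.

    Stands in for the manual clot tracing of the physical experiment; a
    hand-drawn mask file may be supplied instead wherever a clot mask is
    consumed.
    """
    image_like = image.pixels[lumen.pixels]
    if image_like.size == 0:
        raise UndefinedCentroidError("empty lumen mask")
    if np.ptp(image_like) == 0:
        raise DegenerateHistogramError("lumen interior is constant")
    thr = threshold_otsu(image_like)
    raw = (image.pixels > thr) & lumen.pixels
    raw = binary_fill_holes(_remove_specks(raw, 5))
    if raw.any():
        lab = label(raw)
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        raw = lab == counts.argmax()
    return BinaryMask(raw, image.spacing, image.origin)


def component_centroid(mask: BinaryMask) -> np.ndarray:
    """Unweighted mean of member-pixel world coordinates (mm)."""
    if mask.is_empty():
        raise UndefinedCentroidError("centroid of an empty mask is undefined")
    return mask.world_coords().mean(axis=0)


def dice(A: BinaryMask, B: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) in [0, 1]."""
    A.require_same_geometry(B)
    na, nb = A.count, B.count
    if na + nb == 0:
        raise ValueError("Dice of two empty masks is undefined")
    inter = int((A.pixels & B.pixels).sum())
    return 2.0 * inter / (na + nb)


def hausdorff(A: BinaryMask, B: BinaryMask, mode: str = "directed") -> float:
    """Hausdorff distance (mm) between member-pixel center sets.

    ``directed`` is max over A of the nearest-neighbour distance into B;
    ``symmetric`` is the max of both directions.  Masks need not share a
    grid (world coordinates are compared), but both must be non-empty.
    """
    if mode not in ("directed", "symmetric"):
        raise ValueError("mode must be 'directed' or 'symmetric'")
    if A.is_empty() or B.is_empty():
        raise ValueError("Hausdorff distance requires non-empty masks")
    pa, pb = A.world_coords(), B.world_coords()
    d_ab = cKDTree(pb).query(pa)[0].max()
    if mode == "directed":
        return float(d_ab)
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


@dataclass
class RigidTransform2D:
    """p_fixed = scale * R(rotation) @ p_moving + translation (mm)."""

    rotation: float                  # radians
    translation: np.ndarray          # (2,) mm
    scale: float = 1.0
    residual_rms: float = 0.0

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float)
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.translation[None, :]

    def inverse(self) -> "RigidTransform2D":
        inv_scale = 1.0 / self.scale
        c, s = np.cos(-self.rotation), np.sin(-self.rotation)
        Rinv = inv_scale * np.array([[c, -s], [s, c]])
        return RigidTransform2D(
            rotation=-self.rotation,
            translation=-(Rinv @ self.translation),
            scale=inv_scale,
        )

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(rotation=0.0, translation=np.zeros(2))


def register_fiducials(
    moving_points: np.ndarray,
    fixed_points: np.ndarray,
    allow_scale: bool = False,
) -> RigidTransform2D:
    """Least-squares rigid (optionally similarity) fit of matched pairs.

    Umeyama/Kabsch closed form: minimizes the mean squared distance between
    transformed moving points and fixed points; reports the residual RMS.
    """
    mov = np.atleast_2d(np.asarray(moving_points, dtype=float))
    fix = np.atleast_2d(np.asarray(fixed_points, dtype=float))
    if mov.shape != fix.shape or mov.shape[1] != 2:
        raise ValueError("matched (K, 2) point sets required")
    if mov.shape[0] < 2:
        raise ValueError("need at least 2 matched fiducial pairs")
    mu_m, mu_f = mov.mean(axis=0), fix.mean(axis=0)
    dm, df = mov - mu_m, fix - mu_f
    spread = np.linalg.norm(dm, axis=1).max()
    if spread < 1e-9 or np.linalg.norm(df, axis=1).max() < 1e-9:
        raise ValueError("degenerate (coincident) fiducial configuration")
    H = df.T @ dm
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    R = U @ D @ Vt
    if allow_scale:
        var_m = (dm**2).sum() / mov.shape[0]
        scale = float((S * np.diag(D)).sum() / mov.shape[0] / var_m)
    else:
        scale = 1.0
    rotation = float(np.arctan2(R[1, 0], R[0, 0]))
    translation = mu_f - scale * (R @ mu_m)
    tf = RigidTransform2D(rotation=rotation, translation=translation, scale=scale)
    resid = tf.apply(mov) - fix
    tf.residual_rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return tf


def transform_mask(
    mask: BinaryMask, transform: RigidTransform2D, reference: BinaryMask
) -> BinaryMask:
    """Resample ``mask`` through ``transform`` onto the grid of ``reference``
    by nearest-neighbour lookup (keeps the mask strictly binary)."""
    n0, n1 = reference.shape
    I, J = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    world = reference.origin[None, :] + np.column_stack(
        [I.ravel(), J.ravel()]
    ) * reference.spacing[None, :]
    src = transform.inverse().apply(world)
    idx = np.round((src - mask.origin[None, :]) / mask.spacing[None, :]).astype(int)
    ok = (
        (idx[:, 0] >= 0) & (idx[:, 0] < mask.shape[0])
        & (idx[:, 1] >= 0) & (idx[:, 1] < mask.shape[1])
    )
    out = np.zeros(n0 * n1, dtype=bool)
    out[ok] = mask.pixels[idx[ok, 0], idx[ok, 1]]
    return BinaryMask(out.reshape(n0, n1), reference.spacing, reference.origin)


@dataclass
class TargetingRecord:
    """Focus-to-centroid targeting error at one insonation stop."""

    location_index: int
    focus: np.ndarray            # (2,) mm
    region_centroid: np.ndarray  # (2,) mm
    error: float                 # mm

    def __post_init__(self):
        self.focus = np.asarray(self.focus, dtype=float)
        self.region_centroid = np.asarray(self.region_centroid, dtype=float)


def targeting_error(
    focus, region: BinaryMask, location_index: int = 0
) -> TargetingRecord:
    """Euclidean distance (mm) between the therapy focus and the centroid of
    a segmented region."""
    focus = np.asarray(focus, dtype=float)
    centroid = component_centroid(region)
    err = float(np.linalg.norm(focus - centroid))
    return TargetingRecord(
        location_index=location_index, focus=focus,
        region_centroid=centroid, error=err,
    )
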