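"""Synthetic inputs with known ground truth.

Three generators feed the pipeline:

* RF channel data from broadband point emitters (stand-ins for bubble-cloud
  acoustic emissions) received on a linear array, with 1/R spherical
  spreading, per-emitter onsets, and white Gaussian noise at a stated SNR.
* A vessel-phantom cross-section image: bright latex wall annulus (6.35 mm
  inner diameter, 0.79 mm wall), dark lumen interior, mid-intensity clot
  disk (~2 mm radius), with multiplicative speckle-like noise.  Emulation is
  at the intensity-map level, not RF level: downstream operations consume
  grayscale intensity only.
* A liquefaction-outcome mask: the union of per-stop footprint ellipses,
  perturbed by seeded jitter and eroded at the boundary to mimic the
  under-treatment seen in gross sections, plus fiducials outside the mask.

Every generator is deterministic given its seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield
from typing import Optional

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

from .field_model import FootprintEllipse, Medium
from .images import BinaryMask, GrayscaleImage
from .pam import ArrayGeometry, ChannelData
from .path_planning import InsonationPlan

__all__ = [
    "EmitterSet",
    "PhantomTruth",
    "gaussian_pulse",
    "simulate_emissions",
    "make_vessel_image",
    "footprint_union_mask",
    "make_liquefaction_truth",
]


@dataclass
class EmitterSet:
    """Broadband point emitters in front of the array (positions in mm)."""

    positions: np.ndarray                 # (K, 3) mm
    amplitudes: np.ndarray                # (K,) relative
    center_frequency: float = 3e6         # Hz
    fractional_bandwidth: float = 1.0
    onset_times: Optional[np.ndarray] = None   # (K,) s

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        if self.positions.size and self.positions.shape[1] != 3:
            raise ValueError("emitter positions must be (K, 3) mm")
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, float))
        if (self.amplitudes <= 0).any():
            raise ValueError("amplitudes must be positive")
        if self.onset_times is None:
            self.onset_times = np.zeros(self.amplitudes.shape)
        else:
            self.onset_times = np.atleast_1d(np.asarray(self.onset_times, float))

    @property
    def n_emitters(self) -> int:
        return 0 if self.positions.size == 0 else self.positions.shape[0]

    @classmethod
    def empty(cls) -> "EmitterSet":
        return cls(positions=np.zeros((0, 3)), amplitudes=np.ones(0))


def gaussian_pulse(
    t: np.ndarray, center_frequency: float, fractional_bandwidth: float
) -> np.ndarray:
    """Gaussian-windowed sinusoid whose -6 dB spectral full width equals
    ``fractional_bandwidth * center_frequency``."""
    bw = fractional_bandwidth * center_frequency
    sigma_t = 2.0 * np.sqrt(2 * np.log(2)) / (2 * np.pi * bw)
    return np.exp(-(t**2) / (2 * sigma_t**2)) * np.sin(2 * np.pi * center_frequency * t)


def simulate_emissions(
    emitters: EmitterSet,
    geom: ArrayGeometry,
    medium: Medium,
    fs: float = 31.25e6,
    duration: float = 16e-6,
    snr_db: float = np.inf,
    seed: int = 0,
    t0: float = 0.0,
    frame_id: int = 0,
) -> ChannelData:
    """Channel data: sum over emitters of (amplitude / R_n) * pulse(t - R_n/c
    - onset), plus white Gaussian noise at the stated SNR.

    The pulse is evaluated analytically at the exact retarded times (no
    interpolation error).  SNR is defined on mean signal power across the
    record; with no emitters the noise variance is 10^(-snr/10) relative to
    a unit reference.
    """
    if fs < 2 * emitters.center_frequency:
        raise ValueError("sampling rate must satisfy Nyquist for the pulse")
    rng = np.random.default_rng(seed)
    n_s = int(round(duration * fs))
    t = t0 + np.arange(n_s) / fs
    c = medium.sound_speed
    samples = np.zeros((geom.n_elements, n_s))
    sigma_t = 2.0 * np.sqrt(2 * np.log(2)) / (
        2 * np.pi * emitters.fractional_bandwidth * emitters.center_frequency
    )
    for k in range(emitters.n_emitters):
        pos_m = emitters.positions[k] * 1e-3
        R = np.linalg.norm(geom.element_positions - pos_m[None, :], axis=1)
        arrivals = R / c + emitters.onset_times[k]
        if (arrivals + 3 * sigma_t > t0 + duration).any() or (
            arrivals - 3 * sigma_t < t0
        ).any():
            warnings.warn(
                "emitter arrival clipped by the record window", stacklevel=2
            )
        tau = t[None, :] - arrivals[:, None]
        samples += (emitters.amplitudes[k] / R)[:, None] * gaussian_pulse(
            tau, emitters.center_frequency, emitters.fractional_bandwidth
        )
    if np.isfinite(snr_db):
        sig_power = float(np.mean(samples**2))
        ref = sig_power if sig_power > 0 else 1.0
        noise_sigma = np.sqrt(ref * 10 ** (-snr_db / 10))
        samples = samples + rng.normal(0.0, noise_sigma, samples.shape)
    return ChannelData(samples=samples, sampling_rate=fs, t0=t0, frame_id=frame_id)


@dataclass
class PhantomTruth:
    """Ground truth of the vessel/clot phantom cross-section (mm)."""

    lumen_center: np.ndarray = dfield(
        default_factory=lambda: np.array([0.0, 60.0])
    )
    lumen_inner_diameter: float = 6.35
    wall_thickness: float = 0.79
    clot_center: Optional[np.ndarray] = None
    clot_radius: float = 2.0
    fiducials: Optional[np.ndarray] = None
    liquefied_mask: Optional[BinaryMask] = None

    def __post_init__(self):
        self.lumen_center = np.asarray(self.lumen_center, dtype=float)
        if self.clot_center is not None:
            self.clot_center = np.asarray(self.clot_center, dtype=float)
            r_free = self.lumen_inner_diameter / 2 - self.clot_radius
            if np.linalg.norm(self.clot_center - self.lumen_center) > r_free + 1e-9:
                raise ValueError("clot must lie inside the lumen")


# intensity levels of the noise-free vessel image
_LEVEL_BACKGROUND = 0.60
_LEVEL_WALL = 0.95
_LEVEL_LUMEN = 0.05
_LEVEL_CLOT = 0.45


def make_vessel_image(
    truth: Optional[PhantomTruth] = None,
    spacing: float = 0.1,
    noise_seed: Optional[int] = 0,
    speckle_cv: float = 0.15,
    margin: float = 3.0,
) -> tuple[GrayscaleImage, PhantomTruth]:
    """Synthetic B-mode-like cross-section of the model vessel.

    Bright wall annulus, dark lumen interior, mid-intensity clot disk, and
    (optionally) smoothed multiplicative speckle-like noise.  ``noise_seed``
    None disables the noise entirely.
    """
    if spacing > 0.2:
        raise ValueError("spacing must be <= 0.2 mm to resolve the wall")
    truth = truth or PhantomTruth(clot_center=np.array([0.0, 60.0]))
    cx, cz = truth.lumen_center
    r_in = truth.lumen_inner_diameter / 2
    r_out = r_in + truth.wall_thickness
    half = r_out + margin
    ax0 = np.arange(cx - half, cx + half + spacing / 2, spacing)
    ax1 = np.arange(cz - half, cz + half + spacing / 2, spacing)
    X, Z = np.meshgrid(ax0, ax1, indexing="ij")
    rr = np.hypot(X - cx, Z - cz)
    img = np.full(X.shape, _LEVEL_BACKGROUND)
    img[rr <= r_out] = _LEVEL_WALL
    img[rr <= r_in] = _LEVEL_LUMEN
    if truth.clot_center is not None:
        rc = np.hypot(X - truth.clot_center[0], Z - truth.clot_center[1])
        img[rc <= truth.clot_radius] = _LEVEL_CLOT
    if noise_seed is not None and speckle_cv > 0:
        rng = np.random.default_rng(noise_seed)
        field = rng.normal(0.0, 1.0, img.shape)
        field = gaussian_filter(field, sigma=1.0)
        field /= max(field.std(), 1e-12)
        img = img * (1.0 + speckle_cv * field)
        img = np.clip(img, 0.0, None)
    image = GrayscaleImage(
        pixels=img, spacing=np.array([spacing, spacing]),
        origin=np.array([ax0[0], ax1[0]]),
    )
    return image, truth


def _ellipse_mask(X, Z, center, minor_mm, major_mm):
    """Supra-threshold footprint ellipse: minor axis along azimuth (axis 0),
    major along range (axis 1)."""
    return ((X - center[0]) / (minor_mm / 2)) ** 2 + (
        (Z - center[1]) / (major_mm / 2)
    ) ** 2 <= 1.0


def footprint_union_mask(
    stops_xy: np.ndarray,
    footprint: FootprintEllipse,
    spacing: float = 0.05,
    margin: float = 2.0,
    extent: Optional[tuple] = None,
) -> BinaryMask:
    """Union of the footprint ellipse stamped at every planned stop
    (the predicted liquefaction area of a treatment plan)."""
    stops = np.atleast_2d(np.asarray(stops_xy, dtype=float))[:, :2]
    if extent is None:
        x0 = stops[:, 0].min() - footprint.minor_axis / 2 - margin
        x1 = stops[:, 0].max() + footprint.minor_axis / 2 + margin
        z0 = stops[:, 1].min() - footprint.major_axis / 2 - margin
        z1 = stops[:, 1].max() + footprint.major_axis / 2 + margin
    else:
        x0, z0, x1, z1 = extent
    n0 = int(np.floor((x1 - x0) / spacing)) + 1
    n1 = int(np.floor((z1 - z0) / spacing)) + 1
    I, J = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    X = x0 + I * spacing
    Z = z0 + J * spacing
    mask = np.zeros(X.shape, dtype=bool)
    for s in stops:
        mask |= _ellipse_mask(X, Z, s, footprint.minor_axis, footprint.major_axis)
    return BinaryMask(
        mask, np.array([spacing, spacing]), np.array([x0, z0])
    )


def make_liquefaction_truth(
    plan_stops_xy: np.ndarray,
    footprint: FootprintEllipse,
    jitter_mm: float = 0.2,
    erosion_px: int = 2,
    seed: int = 0,
    spacing: float = 0.05,
    n_fiducials: int = 4,
    reference: Optional[BinaryMask] = None,
) -> tuple[BinaryMask, np.ndarray]:
    """Simulated *actual* liquefaction mask plus fiducial positions.

    Each stop's footprint ellipse is displaced by seeded Gaussian jitter and
    the union is eroded at the boundary to mimic under-treatment (sections
    typically liquefy slightly less than predicted).  Fiducials are placed
    at the grid corners, outside the mask.  Pass ``reference`` to rasterize
    on an existing grid (e.g. the predicted mask's).
    """
    rng = np.random.default_rng(seed)
    stops = np.atleast_2d(np.asarray(plan_stops_xy, dtype=float))[:, :2]
    jitter = rng.normal(0.0, jitter_mm, stops.shape) if jitter_mm > 0 else 0.0
    moved = stops + jitter
    if reference is None:
        base = footprint_union_mask(stops, footprint, spacing=spacing)
    else:
        base = reference
    n0, n1 = base.shape
    I, J = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    X = base.origin[0] + I * base.spacing[0]
    Z = base.origin[1] + J * base.spacing[1]
    mask = np.zeros((n0, n1), dtype=bool)
    for s in moved:
        mask |= _ellipse_mask(X, Z, s, footprint.minor_axis, footprint.major_axis)
    if erosion_px > 0:
        mask = binary_erosion(mask, iterations=erosion_px)
    corners = np.array(
        [
            [X[0, 0] + 0.5, Z[0, 0] + 0.5],
            [X[-1, 0] - 0.5, Z[0, 0] + 0.5],
            [X[0, 0] + 0.5, Z[0, -1] - 0.5],
            [X[-1, 0] - 0.5, Z[0, -1] - 0.5],
        ]
    )
    fiducials = corners[: max(3, min(n_fiducials, 4))]
    return BinaryMask(mask, base.spacing.copy(), base.origin.copy()), fiducials
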