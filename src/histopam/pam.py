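"""Passive cavitation mapping with the robust Capon beamformer (RCB).

Receive-only RF channel data recorded during histotripsy insonation are
beamformed to a map of the acoustic power radiated by bubble activity.  For
each pixel r the per-channel signals are delay-aligned to r, the broadband
time-domain correlation matrix R_{nm} = int s_n(t) s_m(t) dt is formed over
the full record of duration T_H, and the robust Capon power

    P_RCB(r) = 4 pi d(r)^e / (T_H rho c) * 1 / (a_hat' R^{-1} a_hat)

is assigned, where a_hat is the data-adaptive steering vector obtained by
shrinking the nominal vector a_bar against the eigenspectrum of R within the
uncertainty ball ||a_hat - a_bar||^2 <= epsilon, solved via the Lagrange
multiplier lambda.  With R = U V U' and z = U' a_bar the power kernel reduces
per-eigenvalue to

    a_hat' R^{-1} a_hat = sum_i lambda^2 gamma_i z_i^2 / (1 + lambda gamma_i)^2

and lambda is the root of the monotone constraint
sum_i z_i^2 / (1 + lambda gamma_i)^2 = epsilon.  d(r) is the mean
pixel-to-element distance; the exponent e on d is configurable (default 2,
energy-conserving spherical spreading).  A conventional delay-and-sum (DAS)
power estimate is available as a cross-beamformer baseline.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.fft import next_fast_len
from scipy.optimize import brentq

from .exceptions import (
    GridMismatchError,
    NumericFailureError,
    TruncationError,
    UndefinedCentroidError,
)
from .field_model import Medium
from .images import BinaryMask

__all__ = [
    "ArrayGeometry",
    "ChannelData",
    "SteeredSet",
    "CorrelationMatrix",
    "RCBParams",
    "AcousticPowerMap",
    "steer_signals",
    "correlation_matrix",
    "rcb_power",
    "pam_map",
    "pam_map_stack",
    "frame_average",
    "emission_centroid",
    "one_dB_region",
    "default_map_grid",
]


@dataclass(frozen=True)
class ArrayGeometry:
    """Linear receive array; positions in metres, elements along azimuth (x)."""

    element_positions: np.ndarray   # (N, 3)
    pitch: float
    center_frequency: float = 7.8e6

    def __post_init__(self):
        pos = np.asarray(self.element_positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("element_positions must be (N, 3)")
        if not np.all(np.diff(pos[:, 0]) > 0):
            raise ValueError("elements must be strictly ordered along azimuth")
        object.__setattr__(self, "element_positions", pos)

    @property
    def n_elements(self) -> int:
        return self.element_positions.shape[0]

    @classmethod
    def linear(
        cls, n_elements: int = 128, pitch: float = 0.3e-3,
        center_frequency: float = 7.8e6,
    ) -> "ArrayGeometry":
        """Centered linear array in the z=0 plane facing +z (L11-5v-like)."""
        x = (np.arange(n_elements) - (n_elements - 1) / 2) * pitch
        pos = np.column_stack([x, np.zeros(n_elements), np.zeros(n_elements)])
        return cls(pos, pitch, center_frequency)


@dataclass
class ChannelData:
    """One receive frame of RF samples for every array element."""

    samples: np.ndarray       # (n_elements, n_samples)
    sampling_rate: float      # Hz
    t0: float = 0.0           # s, acquisition clock origin of sample 0
    frame_id: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (n_elements, n_samples)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("channel samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_elements(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record duration T_H (s)."""
        return self.n_samples / self.sampling_rate


@dataclass
class SteeredSet:
    """Channels delay-aligned to a focus point."""

    steered: np.ndarray       # (n_elements, n_samples)
    point: np.ndarray         # (3,) m
    distances: np.ndarray     # (n_elements,) m
    sampling_rate: float

    @property
    def d_mean(self) -> float:
        """Mean element-to-pixel distance d(r) (m)."""
        return float(self.distances.mean())


@dataclass
class CorrelationMatrix:
    matrix: np.ndarray        # (N, N), units signal^2 * s
    duration: float           # T_H, s

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10 * max(1.0, np.abs(self.matrix).max())):
            raise ValueError("correlation matrix must be symmetric")


@dataclass
class RCBParams:
    """Robust-Capon tuning.

    epsilon: steering-vector uncertainty ||a_hat - a_bar||^2 bound; None
        selects 0.1 * n_elements.  Must satisfy 0 < epsilon < n_elements.
    loading: diagonal loading as a fraction of trace(R)/N, for PSD safety.
    d_exponent: exponent on the mean distance in the geometric prefactor.
    bracket_growth: expansion factor for the lambda root bracket.
    """

    epsilon: Optional[float] = None
    loading: float = 1e-6
    d_exponent: int = 2
    db_convention: str = "power"   # "power" (10 log10) | "amplitude" (20 log10)
    bracket_growth: float = 4.0

    def resolve_epsilon(self, n_elements: int) -> float:
        eps = 0.1 * n_elements if self.epsilon is None else self.epsilon
        if not 0 < eps < n_elements:
            raise ValueError("epsilon must lie in (0, n_elements)")
        return eps


@dataclass
class AcousticPowerMap:
    """P_RCB on a 2-D azimuth x range grid (coordinates in mm)."""

    azimuth_mm: np.ndarray
    range_mm: np.ndarray
    power: np.ndarray              # (n_az, n_rng), >= 0
    frames_averaged: int = 1

    def __post_init__(self):
        self.azimuth_mm = np.atleast_1d(np.asarray(self.azimuth_mm, float))
        self.range_mm = np.atleast_1d(np.asarray(self.range_mm, float))
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (self.azimuth_mm.size, self.range_mm.size):
            raise ValueError("power shape must be (n_azimuth, n_range)")
        if (self.power < 0).any():
            raise ValueError("acoustic power must be non-negative")

    def same_grid(self, other: "AcousticPowerMap") -> bool:
        return (
            self.azimuth_mm.size == other.azimuth_mm.size
            and self.range_mm.size == other.range_mm.size
            and np.allclose(self.azimuth_mm, other.azimuth_mm)
            and np.allclose(self.range_mm, other.range_mm)
        )


def default_map_grid():
    """Module default imaging grid: 0.2 mm azimuth x 0.5 mm range spacing
    covering +/-12 mm x 40-80 mm."""
    return np.arange(-12.0, 12.0 + 1e-9, 0.2), np.arange(40.0, 80.0 + 1e-9, 0.5)


def _fractional_delay_fft(samples: np.ndarray, advances_s: np.ndarray, fs: float):
    """Advance each row of ``samples`` by its (non-negative) delay via an FFT
    phase ramp (band-limited interpolation). Zero-padded to curb wrap-around."""
    n_el, n_s = samples.shape
    n_fft = int(2 ** np.ceil(np.log2(2 * n_s)))
    spec = np.fft.rfft(samples, n=n_fft, axis=-1)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    ramp = np.exp(2j * np.pi * freqs[None, :] * advances_s[:, None])
    out = np.fft.irfft(spec * ramp, n=n_fft, axis=-1)[:, :n_s]
    return out


def steer_signals(
    data: ChannelData, point, medium: Medium, geom: ArrayGeometry
) -> SteeredSet:
    """Delay-align all channels to a focus point.

    Each channel n is advanced by (d_n - min_m d_m)/c with band-limited
    (FFT phase-ramp) interpolation, so a wavefront emitted at the point
    arrives simultaneously on all steered channels.
    """
    point = np.asarray(point, dtype=float)
    dists = np.linalg.norm(geom.element_positions - point[None, :], axis=1)
    rel_delays = (dists - dists.min()) / medium.sound_speed
    if rel_delays.max() > data.duration:
        raise TruncationError(
            "relative steering delay exceeds the record length"
        )
    steered = _fractional_delay_fft(data.samples, rel_delays, data.sampling_rate)
    return SteeredSet(
        steered=steered, point=point, distances=dists,
        sampling_rate=data.sampling_rate,
    )


def correlation_matrix(steered: SteeredSet) -> CorrelationMatrix:
    """Broadband time-domain correlation R_{nm} = sum_t s_n s_m * dt."""
    s = steered.steered
    if s.shape[0] < 2 or s.shape[1] < 2:
        raise ValueError("need >= 2 elements and >= 2 samples")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite steered samples")
    dt = 1.0 / steered.sampling_rate
    R = (s @ s.T) * dt
    R = 0.5 * (R + R.T)
    return CorrelationMatrix(matrix=R, duration=s.shape[1] * dt)


def _rcb_denominator(gamma: np.ndarray, z: np.ndarray, eps: float, growth: float):
    """Solve the lambda constraint and return a_hat' R^-1 a_hat."""
    z2 = z**2

    def g(lam):
        return float(np.sum(z2 / (1.0 + lam * gamma) ** 2)) - eps

    if g(0.0) <= 0:
        # nominal vector already inside the uncertainty ball: Capon limit
        return float(np.sum(z2 / gamma))
    hi = 1.0 / (eps * gamma.max())
    for _ in range(200):
        if g(hi) < 0:
            break
        hi *= growth
    else:
        raise NumericFailureError(
            f"lambda root not bracketed; eigenvalues={gamma!r}"
        )
    lam = brentq(g, 0.0, hi, xtol=1e-18, rtol=1e-14)
    return float(np.sum(lam**2 * gamma * z2 / (1.0 + lam * gamma) ** 2))


def rcb_power(
    R: CorrelationMatrix,
    nominal_steering: Optional[np.ndarray] = None,
    params: Optional[RCBParams] = None,
    d_mean: float = 1.0,
    medium: Optional[Medium] = None,
) -> float:
    """Robust Capon acoustic power for one pixel.

    The nominal steering vector defaults to the all-ones vector (channels are
    already delay-aligned), normalized so ||a_bar||^2 = N.
    """
    params = params or RCBParams()
    medium = medium or Medium()
    M = R.matrix
    n = M.shape[0]
    a_bar = np.ones(n) if nominal_steering is None else np.asarray(nominal_steering, float)
    norm2 = float(a_bar @ a_bar)
    if not np.isclose(norm2, n, rtol=1e-6):
        a_bar = a_bar * np.sqrt(n / norm2)
    tr = float(np.trace(M))
    if tr <= 0:
        return 0.0
    eps = params.resolve_epsilon(n)
    Ml = M + (params.loading * tr / n) * np.eye(n)
    gamma, U = np.linalg.eigh(Ml)
    gamma = np.clip(gamma, 0.0, None)
    if gamma.max() <= 0:
        return 0.0
    gamma = np.maximum(gamma, 1e-300)
    z = U.T @ a_bar
    denom = _rcb_denominator(gamma, z, eps, params.bracket_growth)
    if denom <= 0:
        return 0.0
    pre = 4 * np.pi * d_mean**params.d_exponent / (
        R.duration * medium.density * medium.sound_speed
    )
    return pre / denom


def _das_power(
    R: CorrelationMatrix, n: int, d_mean: float, params: RCBParams, medium: Medium
) -> float:
    """Conventional delay-sum-square power: 1' R 1 / N^2 with the same
    geometric prefactor as the RCB estimate."""
    ones = np.ones(n)
    quad = float(ones @ R.matrix @ ones) / n**2
    pre = 4 * np.pi * d_mean**params.d_exponent / (
        R.duration * medium.density * medium.sound_speed
    )
    return max(pre * quad, 0.0)


def pam_map(
    data: ChannelData,
    azimuth_mm: np.ndarray,
    range_mm: np.ndarray,
    geom: ArrayGeometry,
    medium: Optional[Medium] = None,
    params: Optional[RCBParams] = None,
    beamformer: str = "rcb",
) -> AcousticPowerMap:
    """Passive acoustic map of one frame: per-pixel steer, correlate, power."""
    return pam_map_stack(
        [data], azimuth_mm, range_mm, geom, medium, params, beamformer
    )[0]


def pam_map_stack(
    frames: Sequence[ChannelData],
    azimuth_mm: np.ndarray,
    range_mm: np.ndarray,
    geom: ArrayGeometry,
    medium: Optional[Medium] = None,
    params: Optional[RCBParams] = None,
    beamformer: str = "rcb",
) -> list[AcousticPowerMap]:
    """Beamform several frames that share geometry and grid.

    Steering delays depend only on the pixel, so all frames are delayed with
    one batched FFT per pixel; the correlation/eigen step runs per frame.
    """
    if beamformer not in ("rcb", "das"):
        raise ValueError("beamformer must be 'rcb' or 'das'")
    medium = medium or Medium()
    params = params or RCBParams()
    az = np.atleast_1d(np.asarray(azimuth_mm, float))
    rg = np.atleast_1d(np.asarray(range_mm, float))
    n_fr = len(frames)
    if n_fr == 0:
        raise ValueError("no frames given")
    fs = frames[0].sampling_rate
    n_el = frames[0].n_elements
    n_s = frames[0].n_samples
    for f in frames[1:]:
        if f.sampling_rate != fs or f.samples.shape != (n_el, n_s):
            raise GridMismatchError("frames must share shape and sampling rate")
    if n_el != geom.n_elements:
        raise ValueError("channel count does not match array geometry")
    stack = np.stack([f.samples for f in frames])          # (F, N, T)
    dt = 1.0 / fs
    T_H = n_s * dt
    c = medium.sound_speed
    elem = geom.element_positions
    # per-pixel relative steering delays for the whole grid, up front, so the
    # FFT padding can be the minimum that prevents circular wrap-around
    pts = np.stack(
        np.meshgrid(az * 1e-3, rg * 1e-3, indexing="ij"), axis=-1
    )                                                      # (na, nr, 2)
    diff_x = pts[..., 0][..., None] - elem[None, None, :, 0]
    diff_z = pts[..., 1][..., None] - elem[None, None, :, 2]
    dists_all = np.sqrt(diff_x**2 + diff_z**2 + elem[None, None, :, 1] ** 2)
    rel_all = (dists_all - dists_all.min(axis=-1, keepdims=True)) / c
    if rel_all.max() > T_H:
        raise TruncationError("relative steering delay exceeds the record length")
    max_shift = int(np.ceil(rel_all.max() * fs))
    n_fft = next_fast_len(n_s + max_shift + 16)
    spec = np.fft.rfft(stack, n=n_fft, axis=-1)            # (F, N, n_fft/2+1)
    freqs = np.fft.rfftfreq(n_fft, d=dt)
    power = np.zeros((n_fr, az.size, rg.size))
    eps = params.resolve_epsilon(n_el)
    ones = np.ones(n_el)
    for i in range(az.size):
        for j in range(rg.size):
            dists = dists_all[i, j]
            rel = rel_all[i, j]
            ramp = np.exp(2j * np.pi * freqs[None, :] * rel[:, None])
            steered = np.fft.irfft(spec * ramp[None, :, :], n=n_fft, axis=-1)[
                ..., :n_s
            ]                                              # (F, N, T)
            Rs = (steered @ steered.transpose(0, 2, 1)) * dt
            d_mean = float(dists.mean())
            pre = 4 * np.pi * d_mean**params.d_exponent / (
                T_H * medium.density * c
            )
            if beamformer == "das":
                quad = np.einsum("n,fnm,m->f", ones, Rs, ones) / n_el**2
                power[:, i, j] = np.maximum(pre * quad, 0.0)
                continue
            tr = np.trace(Rs, axis1=1, axis2=2)
            Rl = Rs + (params.loading * tr / n_el)[:, None, None] * np.eye(n_el)
            gammas, Us = np.linalg.eigh(Rl)
            for f in range(n_fr):
                if tr[f] <= 0:
                    continue
                gamma = np.clip(gammas[f], 1e-300, None)
                z = Us[f].T @ ones
                try:
                    denom = _rcb_denominator(gamma, z, eps, params.bracket_growth)
                except NumericFailureError as exc:
                    raise NumericFailureError(
                        f"pixel ({i}, {j}), frame {f}: {exc}"
                    ) from exc
                power[f, i, j] = pre / denom if denom > 0 else 0.0
    return [
        AcousticPowerMap(az.copy(), rg.copy(), power[f], frames_averaged=1)
        for f in range(n_fr)
    ]


def frame_average(maps: Sequence[AcousticPowerMap]) -> AcousticPowerMap:
    """Pixel-wise arithmetic mean over frames sharing a grid."""
    if len(maps) == 0:
        raise ValueError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if not first.same_grid(m):
            raise GridMismatchError("maps do not share a grid")
    mean = np.mean([m.power for m in maps], axis=0)
    return AcousticPowerMap(
        first.azimuth_mm.copy(), first.range_mm.copy(), mean,
        frames_averaged=int(sum(m.frames_averaged for m in maps)),
    )


def emission_centroid(pmap: AcousticPowerMap) -> np.ndarray:
    """Power-weighted mean (azimuth, range) position in mm."""
    total = pmap.power.sum()
    if total <= 0:
        raise UndefinedCentroidError("centroid of an all-zero map is undefined")
    A, Rg = np.meshgrid(pmap.azimuth_mm, pmap.range_mm, indexing="ij")
    return np.array(
        [(pmap.power * A).sum() / total, (pmap.power * Rg).sum() / total]
    )


def one_dB_region(pmap: AcousticPowerMap, convention: str = "power") -> BinaryMask:
    """Pixels within 1 dB of the peak emission level.

    ``convention`` selects the decibel scale: "power" (10 log10, threshold
    peak * 10^-0.1) or "amplitude" (20 log10, threshold peak * 10^-0.05).
    """
    pk = pmap.power.max()
    if pk <= 0:
        raise UndefinedCentroidError("1-dB region of an all-zero map is undefined")
    if convention == "power":
        thr = pk * 10 ** (-1 / 10)
    elif convention == "amplitude":
        thr = pk * 10 ** (-1 / 20)
    else:
        raise ValueError("convention must be 'power' or 'amplitude'")
    spacing = np.array(
        [
            np.diff(pmap.azimuth_mm).mean() if pmap.azimuth_mm.size > 1 else 1.0,
            np.diff(pmap.range_mm).mean() if pmap.range_mm.size > 1 else 1.0,
        ]
    )
    origin = np.array([pmap.azimuth_mm[0], pmap.range_mm[0]])
    return BinaryMask(pmap.power >= thr, spacing, origin)
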