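"""Polarized-light-imaging analysis: sinusoid fitting and orientation maps.

A rotation series of a birefringent section between polarizers produces,
at each pixel, an intensity sinusoid in the filter rotation angle rho.
Its phase encodes the in-plane fiber direction phi and its normalized
amplitude the retardance delta, which relates to the out-of-plane
inclination alpha through delta = delta_max * cos^2(alpha).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import InsufficientDataError

log = logging.getLogger(__name__)

CROSSED_DEFAULT_ANGLES = tuple(float(a) for a in range(0, 90, 10))        # 9
QUARTER_DEFAULT_ANGLES = tuple(float(a) for a in range(0, 180, 20))       # 9


@dataclass(frozen=True)
class PLIProtocol:
    """Acquisition protocol for one rotation series."""

    mode: str                              # "crossed" | "quarter_wave"
    rotation_angles: tuple = None          # degrees
    pixel_size: tuple = (64.0, 64.0)       # micrometres
    section_thickness: float = 100.0       # micrometres
    delta_max: float = np.pi / 2           # max retardance, radians

    def __post_init__(self):
        if self.mode not in ("crossed", "quarter_wave"):
            raise ValueError(f"unknown PLI mode {self.mode!r}")
        if self.rotation_angles is None:
            angles = (CROSSED_DEFAULT_ANGLES if self.mode == "crossed"
                      else QUARTER_DEFAULT_ANGLES)
            object.__setattr__(self, "rotation_angles", angles)
        else:
            object.__setattr__(self, "rotation_angles",
                               tuple(float(a) for a in self.rotation_angles))
        if len(self.rotation_angles) == 0:
            raise ValueError("rotation angle list is empty")
        if not 0 < self.delta_max <= np.pi / 2:
            raise ValueError("delta_max must lie in (0, pi/2] for an "
                             "invertible amplitude-inclination relation")


@dataclass
class PLIStack:
    """One rotation series: an image per filter angle."""

    images: np.ndarray      # (n_angles, H, W)
    protocol: PLIProtocol

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_angles, H, W) array")
        if self.images.shape[0] != len(self.protocol.rotation_angles):
            raise ValueError(
                f"{self.images.shape[0]} images for "
                f"{len(self.protocol.rotation_angles)} rotation angles")

    @property
    def shape(self):
        return self.images.shape[1:]


@dataclass
class PLIDirectionMap:
    """Recovered orientation maps; values are defined only where valid."""

    direction: np.ndarray     # (H, W) degrees in [0, 180)
    inclination: np.ndarray   # (H, W) degrees in [0, 90], unsigned
    amplitude: np.ndarray     # (H, W) >= 0
    offset: np.ndarray        # (H, W)
    valid: np.ndarray         # (H, W) bool
    max_intensity: np.ndarray  # (H, W)


def fit_sinusoid(rotation_angles, intensities):
    """Least-squares fit of I(rho) = a + b sin(2 rho + c) per pixel.

    ``intensities`` may be shaped (n,) for one pixel or (n, ...) for an
    image stack. Returns (a, b, c_deg, phase_defined): b >= 0, c wrapped
    to [0, 360); where b falls below machine tolerance the phase is
    flagged undefined (c = NaN there).
    """
    rho = np.deg2rad(np.asarray(rotation_angles, dtype=float))
    if rho.size < 3:
        raise InsufficientDataError("need at least 3 rotation angles")
    if len(np.unique(rho)) != rho.size:
        raise ValueError("rotation angles must be distinct")
    I = np.asarray(intensities, dtype=float)
    if I.shape[0] != rho.size:
        raise ValueError("intensity leading dimension must match angle count")

    # I = a + p sin(2rho) + q cos(2rho), with p = b cos c, q = b sin c
    X = np.stack([np.ones_like(rho), np.sin(2 * rho), np.cos(2 * rho)], axis=1)
    flat = I.reshape(rho.size, -1)
    coef, *_ = np.linalg.lstsq(X, flat, rcond=None)
    a = coef[0].reshape(I.shape[1:])
    p = coef[1].reshape(I.shape[1:])
    q = coef[2].reshape(I.shape[1:])
    b = np.hypot(p, q)
    scale = max(float(np.max(np.abs(flat))), 1.0)
    defined = b > 1e-12 * scale
    with np.errstate(invalid="ignore"):
        c = np.degrees(np.arctan2(q, p)) % 360.0
    c = np.where(defined, c, np.nan)
    if I.ndim == 1:
        return float(a), float(b), float(c), bool(defined)
    return a, b, c, defined


def estimate_orientation(crossed: PLIStack, quarter: PLIStack,
                         noise_floor: float | None = None) -> PLIDirectionMap:
    """Per-pixel fiber direction and inclination from the two filter sets.

    The quarter-wave series I = I0/2 (1 + sin(2(rho - phi)) sin(delta))
    gives the 180-degree-unique direction phi from the sinusoid phase and
    sin(delta) = amplitude / offset; inclination follows from
    delta = delta_max cos^2(alpha). Pixels whose amplitude falls below
    the noise floor (default: 3x a robust residual estimate) are flagged
    invalid — steep or unmyelinated structures.
    """
    if crossed.shape != quarter.shape:
        raise ValueError("crossed and quarter-wave stacks have different shapes")
    delta_max = quarter.protocol.delta_max
    if delta_max is None:
        raise ValueError("delta_max is not configured on the protocol")

    a, b, c, defined = fit_sinusoid(quarter.protocol.rotation_angles,
                                    quarter.images)

    # b sin(2rho + c) == (I0/2) sin(delta) sin(2rho - 2phi)  =>  phi = -c/2
    with np.errstate(invalid="ignore"):
        phi = (-c / 2.0) % 180.0

    if noise_floor is None:
        rho = np.deg2rad(np.asarray(quarter.protocol.rotation_angles))
        pred = (a[None] + b[None] * np.sin(2 * rho[:, None, None]
                                           + np.deg2rad(np.where(defined, c, 0.0))[None]))
        resid = quarter.images - pred
        mad = np.median(np.abs(resid - np.median(resid)))
        noise_floor = 3.0 * 1.4826 * mad
    valid = defined & (b > noise_floor)

    with np.errstate(invalid="ignore", divide="ignore"):
        sin_delta = np.clip(np.where(a > 0, b / a, 0.0), 0.0, 1.0)
        delta = np.arcsin(sin_delta)
        # arcsin is infinitely steep at 1: float noise in b/a would map
        # in-plane fibers to a spurious ~0.01 deg inclination
        delta = np.where(1.0 - sin_delta < 1e-12, delta_max, delta)
        ratio = np.clip(delta / delta_max, 0.0, 1.0)
        alpha = np.degrees(np.arccos(np.sqrt(ratio)))

    return PLIDirectionMap(direction=np.where(valid, phi, np.nan),
                           inclination=np.where(valid, alpha, np.nan),
                           amplitude=b, offset=a, valid=valid,
                           max_intensity=maximum_intensity_map(crossed))


def maximum_intensity_map(stack: PLIStack) -> np.ndarray:
    """Per-pixel maximum over the rotation sequence."""
    return stack.images.max(axis=0)


def orientation_to_hsv(dmap: PLIDirectionMap) -> np.ndarray:
    """HSV-coded orientation image: direction = hue, inclination = saturation.

    In-plane fibers (inclination 0) are fully saturated; steep fibers
    fade to white. Invalid pixels are black. Returns float RGB in [0, 1].
    """
    h = np.where(dmap.valid, dmap.direction, 0.0) / 180.0
    s = np.where(dmap.valid, np.cos(np.deg2rad(
        np.where(dmap.valid, dmap.inclination, 90.0))), 0.0)
    v = dmap.valid.astype(float)

    i = np.floor(h * 6.0).astype(int) % 6
    f = h * 6.0 - np.floor(h * 6.0)
    p = v * (1 - s)
    q = v * (1 - f * s)
    t = v * (1 - (1 - f) * s)
    rgb = np.choose(i[..., None], [
        np.stack([v, t, p], -1), np.stack([q, v, p], -1),
        np.stack([p, v, t], -1), np.stack([p, q, v], -1),
        np.stack([t, p, v], -1), np.stack([v, p, q], -1)])
    return np.clip(rgb, 0.0, 1.0)
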