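"""Synthetic curved-nucleus phantom with planted ground truth.

The phantom is a tube swept along a planar circular arc (the nucleus'
longitudinal axis), filled with two orthogonal fiber compartments: one
tangential to the arc and one radial (in-plane, pointing away from the
arc center). The radial volume fraction follows a smooth schedule along
arc length that plants two microstructural boundaries:

* at arc fraction ``f1`` the dominant orientation switches from
  tangential to radial (the 45-degree boundary), and
* around arc fraction ``f2`` a narrow tangential-dominant notch produces
  a local minimum of the radiality profile (the head boundary), with the
  orientation turning radial again toward the anterior tip.

Arc length runs from the posterior end (s = 0) to the anterior tip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError, DWIVolume, GradientScheme

log = logging.getLogger(__name__)

# default zeppelin eigenvalues (axial, radial, radial) in mm^2/s
DEFAULT_EIGENVALUES = (1.7e-3, 0.3e-3, 0.3e-3)
BACKGROUND_DIFFUSIVITY = 0.7e-3  # isotropic, avoids FA artifacts at the edge


class DegenerateGeometryError(ConfigurationError):
    pass


@dataclass
class CompartmentConfig:
    """Volume-fraction schedule of the radial compartment along the arc.

    ``radial_lo``/``radial_hi`` are the baseline fractions in the
    tangential- and radial-dominant zones; the logistic transition is
    centred on the first planted boundary with width ``transition_width``
    (as a fraction of total arc length). A Gaussian notch of depth down
    to ``notch_lo`` and width ``notch_sigma`` centred on the second
    boundary plants the local minimum near the head.
    """

    eigenvalues: tuple = DEFAULT_EIGENVALUES
    radial_lo: float = 0.15
    radial_hi: float = 0.85
    transition_width: float = 0.02
    notch_lo: float = 0.20
    notch_sigma: float = 0.015

    def __post_init__(self):
        ev = tuple(float(e) for e in self.eigenvalues)
        if len(ev) != 3 or any(e <= 0 for e in ev):
            raise ConfigurationError("eigenvalues must be three positive values")
        if abs(ev[1] - ev[2]) > 1e-15:
            raise ConfigurationError(
                "compartment tensors must be axially symmetric (lambda2 == lambda3)"
            )
        for name in ("radial_lo", "radial_hi", "notch_lo"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.radial_lo >= self.radial_hi:
            raise ConfigurationError("radial_lo must be below radial_hi")

    def radial_fraction(self, arc_fraction: np.ndarray, f1: float, f2: float
                        ) -> np.ndarray:
        u = np.asarray(arc_fraction, dtype=float)
        base = self.radial_lo + (self.radial_hi - self.radial_lo) / (
            1.0 + np.exp(-(u - f1) / self.transition_width))
        if self.radial_hi > 0:
            depth = 1.0 - self.notch_lo / self.radial_hi
        else:
            depth = 0.0
        notch = 1.0 - depth * np.exp(-0.5 * ((u - f2) / self.notch_sigma) ** 2)
        return np.clip(base * notch, 0.0, 1.0)


@dataclass
class PhantomTruth:
    """Ground truth behind a synthetic nucleus phantom."""

    mask: np.ndarray                 # (X, Y, Z) bool
    affine: np.ndarray               # 4x4 voxel -> world (mm)
    voxel_size: tuple
    arc: np.ndarray                  # (m, 3) centerline points, posterior first
    directions: np.ndarray           # (n_vox, 2, 3) unit vectors (tangential, radial)
    fractions: np.ndarray            # (n_vox, 2) volume fractions, sum to 1
    eigenvalues: np.ndarray          # (3,) per-compartment tensor eigenvalues
    arc_length_per_voxel: np.ndarray  # (n_vox,) projected arc length, mm
    planted_boundaries: tuple        # (s1, s2) arc lengths in mm, s1 < s2
    segment_labels: np.ndarray       # (X, Y, Z) int, 0 outside mask, 1/2/3 inside
    ac_point: np.ndarray             # (3,) anterior-commissure surrogate, mm
    total_arc_length: float = field(default=0.0)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def dominant_directions(self) -> np.ndarray:
        """Per-voxel direction of the larger-fraction compartment."""
        idx = np.argmax(self.fractions, axis=1)
        return self.directions[np.arange(len(idx)), idx]


def make_cn_phantom(arc_radius: float = 25.0,
                    arc_span_deg: float = 120.0,
                    tube_radius: float = 4.0,
                    voxel_size: float = 1.0,
                    boundaries: tuple = (0.45, 0.75),
                    compartment_config: CompartmentConfig | None = None,
                    margin: float = 3.0) -> PhantomTruth:
    """Build the curved-nucleus phantom with planted boundaries.

    Parameters
    ----------
    boundaries:
        The two planted boundaries as fractions of total arc length,
        ``0 < f1 < f2 < 1``.
    """
    f1, f2 = boundaries
    if not (0.0 < f1 < f2 < 1.0):
        raise ConfigurationError(
            f"boundary fractions must satisfy 0 < f1 < f2 < 1, got ({f1}, {f2})")
    if arc_radius <= 0 or arc_span_deg <= 0:
        raise ConfigurationError("arc radius and span must be positive")
    if tube_radius < voxel_size:
        raise DegenerateGeometryError(
            f"tube radius {tube_radius} below one voxel ({voxel_size})")
    cfg = compartment_config or CompartmentConfig()

    span = np.deg2rad(arc_span_deg)
    # arc in the y-z (sagittal) plane, centred on theta = pi/2 so that the
    # tube bends like the nucleus head+body; posterior end at theta_min
    theta_min = np.pi / 2 - span / 2
    theta_max = np.pi / 2 + span / 2

    n_arc = 200
    thetas = np.linspace(theta_min, theta_max, n_arc)
    pad = tube_radius + margin
    arc_y = arc_radius * np.cos(thetas)
    arc_z = arc_radius * np.sin(thetas)
    y_lo, y_hi = arc_y.min() - pad, arc_y.max() + pad
    z_lo, z_hi = arc_z.min() - pad, arc_z.max() + pad
    x_lo, x_hi = -pad, pad

    nx = int(np.ceil((x_hi - x_lo) / voxel_size)) + 1
    ny = int(np.ceil((y_hi - y_lo) / voxel_size)) + 1
    nz = int(np.ceil((z_hi - z_lo) / voxel_size)) + 1
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = (x_lo, y_lo, z_lo)

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    xs = ii * voxel_size + x_lo
    ys = jj * voxel_size + y_lo
    zs = kk * voxel_size + z_lo

    # arc center (== AC surrogate) sits at the world origin
    ac_point = np.zeros(3)
    r_inplane = np.hypot(ys, zs)
    theta_vox = np.arctan2(zs, ys)
    dist = np.sqrt((r_inplane - arc_radius) ** 2 + xs ** 2)
    mask = (dist <= tube_radius) & (theta_vox >= theta_min) & (theta_vox <= theta_max)
    if not mask.any():
        raise DegenerateGeometryError("empty phantom mask")

    th = theta_vox[mask]
    total_arc = arc_radius * span
    s_vox = arc_radius * (th - theta_min)

    tangential = np.stack([np.zeros_like(th), -np.sin(th), np.cos(th)], axis=1)
    radial = np.stack([np.zeros_like(th), np.cos(th), np.sin(th)], axis=1)
    directions = np.stack([tangential, radial], axis=1)

    fr = cfg.radial_fraction(s_vox / total_arc, f1, f2)
    fractions = np.stack([1.0 - fr, fr], axis=1)

    s1, s2 = f1 * total_arc, f2 * total_arc
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    seg = np.ones(len(s_vox), dtype=np.int16)
    seg[s_vox >= s1] = 2
    seg[s_vox >= s2] = 3
    labels[mask] = seg

    arc_pts = np.stack([np.zeros_like(thetas), arc_y, arc_z], axis=1)
    return PhantomTruth(
        mask=mask,
        affine=affine,
        voxel_size=(voxel_size,) * 3,
        arc=arc_pts,
        directions=directions,
        fractions=fractions,
        eigenvalues=np.asarray(cfg.eigenvalues, dtype=float),
        arc_length_per_voxel=s_vox,
        planted_boundaries=(s1, s2),
        segment_labels=labels,
        ac_point=ac_point,
        total_arc_length=total_arc,
    )


def _compartment_attenuation(bvals: np.ndarray, bvecs: np.ndarray,
                             dirs: np.ndarray, eigenvalues: np.ndarray
                             ) -> np.ndarray:
    """exp(-b g^T D g) for axially symmetric D per (voxel, measurement)."""
    lam_par, lam_perp = eigenvalues[0], eigenvalues[1]
    dots = dirs @ bvecs.T                       # (n_vox, n_meas)
    quad = lam_perp + (lam_par - lam_perp) * dots ** 2
    return np.exp(-bvals[None, :] * quad)


def simulate_dwi(truth: PhantomTruth, scheme: GradientScheme,
                 s0: float = 1.0, noise_sigma: float = 0.0,
                 rng_seed: int = 0) -> DWIVolume:
    """Multi-tensor forward simulation with optional Rician noise.

    Outside the mask the signal follows an isotropic compartment with
    diffusivity ``BACKGROUND_DIFFUSIVITY``.
    """
    if s0 < 0:
        raise ValueError(f"s0 must be non-negative, got {s0}")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")

    bvals = scheme.bvalues
    bvecs = scheme.directions
    n_meas = len(scheme)
    shape = truth.mask.shape

    signal = np.empty(shape + (n_meas,), dtype=float)
    signal[...] = s0 * np.exp(-bvals * BACKGROUND_DIFFUSIVITY)[None, None, None, :]

    att = np.zeros((truth.n_voxels, n_meas))
    for c in range(truth.directions.shape[1]):
        att += truth.fractions[:, c:c + 1] * _compartment_attenuation(
            bvals, bvecs, truth.directions[:, c, :], truth.eigenvalues)
    signal[truth.mask] = s0 * att

    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        n1 = rng.normal(0.0, noise_sigma, signal.shape)
        n2 = rng.normal(0.0, noise_sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)

    return DWIVolume(signal=signal, scheme=scheme, affine=truth.affine,
                     voxel_size=truth.voxel_size)


def simulate_pli_section(direction_map: np.ndarray, inclination_map: np.ndarray,
                         protocol, i0: float = 100.0,
                         noise_sigma: float = 0.0, rng_seed: int = 0):
    """Forward-model a polarimetric rotation series from orientation maps.

    ``direction_map`` is the in-plane fiber angle phi (degrees),
    ``inclination_map`` the out-of-plane angle alpha (degrees, in
    [-90, 90]). Retardance follows delta = delta_max * cos^2(alpha).

    Crossed polarizers:   I(rho) = I0 * sin^2(2(rho - phi)) * sin^2(delta/2)
    With quarter-wave:    I(rho) = I0/2 * (1 + sin(2(rho - phi)) * sin(delta))
    """
    from .pli import PLIStack  # local import to avoid a cycle

    phi = np.deg2rad(np.asarray(direction_map, dtype=float))
    alpha_deg = np.asarray(inclination_map, dtype=float)
    if phi.shape != alpha_deg.shape:
        raise ValueError("direction and inclination maps must have the same shape")
    if np.any(np.abs(alpha_deg) > 90.0):
        raise ValueError("inclination outside [-90, 90] degrees")
    if len(protocol.rotation_angles) == 0:
        raise ValueError("protocol rotation list is empty")

    alpha = np.deg2rad(alpha_deg)
    delta = protocol.delta_max * np.cos(alpha) ** 2

    images = []
    for rho_deg in protocol.rotation_angles:
        rho = np.deg2rad(rho_deg)
        if protocol.mode == "crossed":
            img = i0 * np.sin(2 * (rho - phi)) ** 2 * np.sin(delta / 2) ** 2
        elif protocol.mode == "quarter_wave":
            img = 0.5 * i0 * (1.0 + np.sin(2 * (rho - phi)) * np.sin(delta))
        else:
            raise ValueError(f"unknown protocol mode {protocol.mode!r}")
        images.append(img)
    stack = np.stack(images, axis=0)

    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        stack = stack + rng.normal(0.0, noise_sigma, stack.shape)
    return PLIStack(images=stack, protocol=protocol)
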