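"""Longitudinal axis of the nucleus and radiality-based tri-partition.

The axis is parameterized by the angle of each mask voxel about a
landmark point (the anterior commissure, or a surrogate) measured in the
best-fit plane of the mask. A cubic smoothing spline of the voxel cloud
against that angular parameter, sampled equidistantly on the parameter
axis, yields sample positions, unit tangents, and cumulative arc length
with s = 0 at the posterior end.

The radiality index at each sample is the mean acute angle (degrees)
between the voxelwise principal diffusion direction and the local spline
tangent: 0 = tangential, 90 = radial. Two boundaries are detected on the
profile — the 45-degree crossing in a central window and the local
minimum in a head window — first at group level on the subject-mean
profile, then refined per subject within a fixed arc-length radius.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import UnivariateSpline

from .core import voxel_to_world

log = logging.getLogger(__name__)


class DegenerateAxisError(ValueError):
    pass


class NoCrossingError(ValueError):
    pass


@dataclass
class LongitudinalSpline:
    """Sampled longitudinal axis with its angular parameterization.

    The centerline is represented in polar form about the landmark: the
    in-plane radial distance rho(t) and the out-of-plane offset nu(t) are
    smoothing splines of the angular parameter t (degrees). This is far
    more stable than per-coordinate splines for an arc-shaped mask.
    """

    ac_point: np.ndarray        # (3,) landmark, mm
    plane_basis: np.ndarray     # (2, 3) in-plane orthonormal basis
    plane_normal: np.ndarray    # (3,)
    param_sign: float           # +1/-1: orients increasing parameter posterior->anterior
    param_offset: float         # degrees subtracted before sign flip (gap alignment)
    params: np.ndarray          # (n,) sample parameters, degrees, strictly increasing
    positions: np.ndarray       # (n, 3) mm
    tangents: np.ndarray        # (n, 3) unit, pointing toward increasing parameter
    arc_length: np.ndarray      # (n,) cumulative, mm, arc_length[0] == 0
    splines: tuple = field(default=None, repr=False)  # (rho(t), nu(t))

    def evaluate(self, t: np.ndarray):
        """Centerline positions and (unnormalized) derivatives at params t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        rho_s, nu_s = self.splines
        theta = np.deg2rad(self.param_offset + self.param_sign * t)
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        e1, e2 = self.plane_basis
        u = cos_t[:, None] * e1 + sin_t[:, None] * e2
        du = (self.param_sign * np.pi / 180.0
              * (-sin_t[:, None] * e1 + cos_t[:, None] * e2))
        rho, nu = rho_s(t), nu_s(t)
        drho = rho_s.deriv()(t)
        dnu = nu_s.deriv()(t)
        pos = self.ac_point + rho[:, None] * u + nu[:, None] * self.plane_normal
        der = (drho[:, None] * u + rho[:, None] * du
               + dnu[:, None] * self.plane_normal)
        return pos, der

    @property
    def n_samples(self) -> int:
        return len(self.params)

    @property
    def total_arc_length(self) -> float:
        return float(self.arc_length[-1])

    def param_of(self, points: np.ndarray) -> np.ndarray:
        """Angular parameter (degrees) of world points, oriented like samples."""
        rel = np.atleast_2d(points) - self.ac_point
        c1 = rel @ self.plane_basis[0]
        c2 = rel @ self.plane_basis[1]
        ang = np.degrees(np.arctan2(c2, c1))
        ang = (ang - self.param_offset) % 360.0
        return self.param_sign * ang

    def arc_length_of(self, points: np.ndarray) -> np.ndarray:
        """Projected arc length of world points (linear interp on samples)."""
        t = self.param_of(points)
        return np.interp(t, self.params, self.arc_length)

    def nearest_sample(self, points: np.ndarray) -> np.ndarray:
        """Index of the parameter-nearest sample for each point."""
        t = self.param_of(points)
        idx = np.searchsorted(self.params, t)
        idx = np.clip(idx, 1, len(self.params) - 1)
        left = self.params[idx - 1]
        right = self.params[idx]
        choose_left = (t - left) <= (right - t)
        return np.where(choose_left, idx - 1, idx)


@dataclass
class RadialityProfile:
    """Per-sample mean angle between principal direction and axis tangent."""

    mean_angle: np.ndarray   # (n,) degrees in [0, 90], NaN where empty
    voxel_count: np.ndarray  # (n,) int
    arc_length: np.ndarray   # (n,) mm
    subject_id: str = ""
    hemisphere: str = ""

    @property
    def n_samples(self) -> int:
        return len(self.mean_angle)


@dataclass
class BoundarySet:
    """The two detected boundaries, as arc lengths from the posterior end."""

    b_45: float            # 45-degree crossing, mm
    b_min: float           # local-minimum position, mm
    level: str             # "group" | "subject"
    search_radius: float = 0.0  # mm; subject level only

    def __post_init__(self):
        if not self.b_45 < self.b_min:
            raise ValueError(
                f"expected b_45 < b_min (posterior->anterior), got "
                f"{self.b_45} >= {self.b_min}")


def _mask_world_coords(mask: np.ndarray, affine: np.ndarray) -> np.ndarray:
    ijk = np.argwhere(np.asarray(mask).astype(bool))
    return voxel_to_world(affine, ijk)


def fit_longitudinal_spline(mask: np.ndarray, affine: np.ndarray,
                            ac_point, n_samples: int = 45,
                            posterior_hint=None,
                            poly_degree: int = 3) -> LongitudinalSpline:
    """Fit the angular-parameter axis model through the mask voxels.

    ``posterior_hint`` (world point) selects which end of the parameter
    range is posterior (s = 0); by default the low-parameter end is used.
    ``poly_degree`` controls the stiffness of the polar centerline model.
    """
    coords = _mask_world_coords(mask, affine)
    if len(coords) == 0:
        raise ValueError("mask is empty")
    ac_point = np.asarray(ac_point, dtype=float)

    # best-fit plane by PCA; normal = direction of least variance
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    w, v = np.linalg.eigh(cov)
    normal = v[:, 0]
    basis = np.stack([v[:, 2], v[:, 1]], axis=0)

    rel = coords - ac_point
    c1 = rel @ basis[0]
    c2 = rel @ basis[1]
    raw = np.degrees(np.arctan2(c2, c1)) % 360.0

    # rotate the angular origin into the largest empty gap so the mask
    # occupies a contiguous, wrap-free angular interval
    order = np.sort(raw)
    gaps = np.diff(np.concatenate([order, [order[0] + 360.0]]))
    g = int(np.argmax(gaps))
    if gaps[g] < 10.0:
        raise DegenerateAxisError("mask wraps fully around the landmark")
    offset = (order[g] + gaps[g] / 2.0) % 360.0
    ang = (raw - offset) % 360.0

    ang_min, ang_max = ang.min(), ang.max()
    if ang_max - ang_min < 10.0:
        raise DegenerateAxisError(
            f"angular range {ang_max - ang_min:.1f} deg < 10 deg")

    # detect disconnected angular components (internal gaps > 5 deg)
    srt = np.sort(ang)
    internal = np.diff(srt)
    if np.any(internal > 5.0):
        splits = np.where(internal > 5.0)[0]
        comps = []
        start = srt[0]
        for s in splits:
            comps.append((float(start), float(srt[s])))
            start = srt[s + 1]
        comps.append((float(start), float(srt[-1])))
        raise DegenerateAxisError(
            f"mask splits into {len(comps)} angular components: {comps}")

    sign = 1.0
    if posterior_hint is not None:
        hint_rel = np.asarray(posterior_hint, dtype=float) - ac_point
        h = np.degrees(np.arctan2(hint_rel @ basis[1], hint_rel @ basis[0]))
        h = (h - offset) % 360.0
        if abs(h - ang_max) < abs(h - ang_min):
            sign = -1.0
    ang = sign * ang

    # fit the centerline in polar form about the landmark: rho(t) and
    # nu(t) vary slowly along an arc-shaped mask, so a stiff low-order
    # model gives far more accurate tangents than free-knot splines,
    # which chase voxel-lattice aliasing noise
    rho_all = np.hypot(c1, c2)
    nu_all = rel @ normal
    deg = min(poly_degree, len(np.unique(ang)) - 1)
    splines = (np.polynomial.Polynomial.fit(ang, rho_all, deg),
               np.polynomial.Polynomial.fit(ang, nu_all, deg))

    t_lo, t_hi = ang.min(), ang.max()
    params = np.linspace(t_lo, t_hi, n_samples)
    spline = LongitudinalSpline(ac_point=ac_point, plane_basis=basis,
                                plane_normal=normal, param_sign=sign,
                                param_offset=offset, params=params,
                                positions=None, tangents=None,
                                arc_length=None, splines=splines)
    positions, deriv = spline.evaluate(params)
    spline.positions = positions
    spline.tangents = deriv / np.linalg.norm(deriv, axis=1, keepdims=True)

    fine = np.linspace(t_lo, t_hi, 20 * n_samples)
    fine_pos, _ = spline.evaluate(fine)
    seglen = np.linalg.norm(np.diff(fine_pos, axis=0), axis=1)
    fine_arc = np.concatenate([[0.0], np.cumsum(seglen)])
    spline.arc_length = np.interp(params, fine, fine_arc)
    return spline


def radiality_profile(field, spline: LongitudinalSpline,
                      mask: np.ndarray | None = None,
                      fa_threshold: float | None = None,
                      subject_id: str = "", hemisphere: str = ""
                      ) -> RadialityProfile:
    """Mean acute angle between principal directions and spline tangents.

    Each masked voxel is assigned to the parameter-nearest spline sample;
    the per-sample mean of arccos(|v . t|) in degrees is returned.
    """
    if mask is None:
        mask = field.mask
    mask = np.asarray(mask).astype(bool)
    if mask.shape != field.mask.shape:
        raise ValueError("mask and tensor field are on different grids")
    if fa_threshold is not None:
        mask = mask & (field.fa >= fa_threshold)

    coords = _mask_world_coords(mask, field.affine)
    dirs = field.principal_dir[mask]
    idx = spline.nearest_sample(coords)

    n = spline.n_samples
    # tangent evaluated at each voxel's own projected parameter, then
    # averaged per sample point (the discrete-sample tangent would floor
    # the profile at ~half the sample spacing in degrees)
    t_vox = np.clip(spline.param_of(coords), spline.params[0],
                    spline.params[-1])
    _, deriv = spline.evaluate(t_vox)
    tangents = deriv / np.linalg.norm(deriv, axis=1, keepdims=True)
    dots = np.abs(np.einsum("ij,ij->i", dirs, tangents))
    angles = np.degrees(np.arccos(np.clip(dots, 0.0, 1.0)))

    mean_angle = np.full(n, np.nan)
    counts = np.bincount(idx, minlength=n)
    sums = np.bincount(idx, weights=angles, minlength=n)
    nonzero = counts > 0
    mean_angle[nonzero] = sums[nonzero] / counts[nonzero]

    n_empty = int(np.sum(~nonzero))
    if n_empty > 0.2 * n:
        warnings.warn(f"{n_empty}/{n} spline samples received no voxels")

    return RadialityProfile(mean_angle=mean_angle, voxel_count=counts,
                            arc_length=spline.arc_length.copy(),
                            subject_id=subject_id, hemisphere=hemisphere)


def _window_to_arc(window, total: float):
    lo, hi = window
    return lo * total, hi * total


def detect_group_boundaries(profiles: list,
                            central_window=(0.25, 0.65),
                            head_window=(0.60, 0.90),
                            smooth: bool = False) -> BoundarySet:
    """Detect the two boundaries on the subject-mean radiality profile.

    ``central_window``/``head_window`` are (lo, hi) fractions of total
    arc length. The 45-degree crossing is linearly interpolated; with
    multiple crossings the one closest to the window center is used. The
    head boundary is the lowest discrete local minimum in its window
    (optionally after 3-sample moving-average smoothing); ties go to the
    posterior-most sample.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    n = profiles[0].n_samples
    for p in profiles:
        if p.n_samples != n:
            raise ValueError("profiles are not on a common parameter grid")
    angles = np.nanmean(np.stack([p.mean_angle for p in profiles]), axis=0)
    arc = np.mean(np.stack([p.arc_length for p in profiles]), axis=0)
    total = arc[-1]

    if smooth:
        kern = np.ones(3) / 3.0
        angles = np.convolve(angles, kern, mode="same")
        angles[0] = (angles[0] * 3 + angles[1]) / 4  # edge renormalization
        angles[-1] = (angles[-1] * 3 + angles[-2]) / 4

    lo, hi = _window_to_arc(central_window, total)
    center = 0.5 * (lo + hi)
    crossings = []
    for i in range(n - 1):
        a0, a1 = angles[i] - 45.0, angles[i + 1] - 45.0
        if np.isnan(a0) or np.isnan(a1):
            continue
        if a0 == 0.0:
            x = arc[i]
        elif a0 * a1 < 0:
            x = arc[i] + (arc[i + 1] - arc[i]) * (-a0) / (a1 - a0)
        else:
            continue
        if lo <= x <= hi:
            crossings.append(x)
    if not crossings:
        in_win = (arc >= lo) & (arc <= hi)
        rng = (np.nanmin(angles[in_win]), np.nanmax(angles[in_win])) \
            if in_win.any() else (np.nan, np.nan)
        raise NoCrossingError(
            f"no 45-degree crossing in central window [{lo:.1f}, {hi:.1f}] mm; "
            f"profile range in window: {rng[0]:.1f}-{rng[1]:.1f} deg")
    if len(crossings) > 1:
        log.info("multiple 45-degree crossings %s; choosing closest to "
                 "window center %.1f mm", crossings, center)
    b45 = min(crossings, key=lambda x: abs(x - center))

    lo_h, hi_h = _window_to_arc(head_window, total)
    in_win = np.where((arc >= lo_h) & (arc <= hi_h))[0]
    if len(in_win) == 0:
        raise ValueError("head window contains no samples")
    minima = []
    for i in in_win:
        left = angles[i - 1] if i > 0 else np.inf
        right = angles[i + 1] if i < n - 1 else np.inf
        if not np.isnan(angles[i]) and angles[i] <= left and angles[i] <= right:
            minima.append(i)
    if not minima:
        minima = [in_win[int(np.nanargmin(angles[in_win]))]]
    vals = np.array([angles[i] for i in minima])
    best = np.min(vals)
    cands = [minima[j] for j in range(len(minima)) if vals[j] == best]
    if len(cands) > 1:
        log.info("tied local minima at samples %s; choosing posterior-most", cands)
    bmin = float(arc[cands[0]])

    return BoundarySet(b_45=float(b45), b_min=bmin, level="group")


def refine_subject_boundaries(profile: RadialityProfile, group: BoundarySet,
                              radius: float = 10.0) -> BoundarySet:
    """Subject-level refinement within +-radius mm of arc length.

    b_45: sample whose angle is closest to 45 degrees; b_min: sample with
    the lowest angle. Ties go to the posterior-most sample.
    """
    if group.level != "group":
        raise ValueError("refinement requires group-level boundaries")
    if radius <= 0:
        raise ValueError("radius must be positive")
    arc = profile.arc_length
    angles = profile.mean_angle

    def window(center):
        lo, hi = center - radius, center + radius
        if lo < arc[0] or hi > arc[-1]:
            warnings.warn(
                f"search window [{lo:.1f}, {hi:.1f}] mm clipped to profile "
                f"extent [{arc[0]:.1f}, {arc[-1]:.1f}] mm")
        sel = np.where((arc >= lo) & (arc <= hi) & ~np.isnan(angles))[0]
        if len(sel) == 0:
            raise ValueError(f"no profile samples within {radius} mm of "
                             f"{center:.1f} mm")
        return sel

    sel = window(group.b_45)
    cost = np.abs(angles[sel] - 45.0)
    b45 = float(arc[sel[np.argmin(cost)]])  # argmin takes first == posterior-most

    sel = window(group.b_min)
    bmin = float(arc[sel[np.argmin(angles[sel])]])

    return BoundarySet(b_45=b45, b_min=bmin, level="subject",
                       search_radius=radius)


def segment_cn(mask: np.ndarray, affine: np.ndarray,
               spline: LongitudinalSpline, boundaries: BoundarySet
               ) -> np.ndarray:
    """Label masked voxels 1 (posterior), 2 (middle), 3 (anterior).

    Labels switch where the voxel's projected arc length crosses b_45 and
    b_min.
    """
    total = spline.total_arc_length
    for b in (boundaries.b_45, boundaries.b_min):
        if not 0.0 <= b <= total:
            raise ValueError(f"boundary {b:.1f} mm outside spline range "
                             f"[0, {total:.1f}] mm")
    mask = np.asarray(mask).astype(bool)
    coords = _mask_world_coords(mask, affine)
    s = spline.arc_length_of(coords)
    lab = np.ones(len(s), dtype=np.int16)
    lab[s >= boundaries.b_45] = 2
    lab[s >= boundaries.b_min] = 3
    labels = np.zeros(mask.shape, dtype=np.int16)
    labels[mask] = lab
    return labels


def choose_typical_subject(cost_matrix: np.ndarray) -> int:
    """Index (0-based) minimizing cumulative off-diagonal deformation cost.

    Ties are broken toward the lowest index.
    """
    c = np.asarray(cost_matrix, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError(f"cost matrix must be square, got {c.shape}")
    off = ~np.eye(c.shape[0], dtype=bool)
    if np.any(c[off] < 0):
        raise ValueError("cost matrix has negative off-diagonal entries")
    sums = np.where(off, c, 0.0).sum(axis=1)
    idx = int(np.argmin(sums))  # argmin breaks ties toward the lowest index
    log.info("typical subject: index %d (row sums %s)", idx, sums)
    return idx
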