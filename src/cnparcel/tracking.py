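"""Deterministic streamline tractography with bundle classification.

Tracking follows a per-voxel direction field (single principal direction
with FA amplitude, or supplied multi-peak fields) with fixed-step Euler
integration, bidirectionally from each seed. A streamline terminates
when it leaves the grid, when the local amplitude falls below the
cutoff, or when the step-to-step turning angle exceeds the discrete
curvature bound theta_max = 2 asin(step / (2 R)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ConfigurationError, containing_voxel

log = logging.getLogger(__name__)


@dataclass
class DirectionField:
    """Per-voxel direction peaks with non-negative amplitudes."""

    directions: np.ndarray   # (X, Y, Z, K, 3) unit vectors (zero rows allowed)
    amplitudes: np.ndarray   # (X, Y, Z, K) >= 0
    affine: np.ndarray       # 4x4

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.directions.ndim != 5 or self.directions.shape[-1] != 3:
            raise ValueError("directions must be (X, Y, Z, K, 3)")
        if self.amplitudes.shape != self.directions.shape[:4]:
            raise ValueError("amplitude shape mismatch")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")
        norms = np.linalg.norm(self.directions, axis=-1)
        nz = norms > 0
        if np.any(np.abs(norms[nz] - 1.0) > 1e-6):
            raise ValueError("direction peaks must be unit norm")

    @property
    def grid_shape(self):
        return self.directions.shape[:3]

    @classmethod
    def from_tensor_field(cls, tf) -> "DirectionField":
        dirs = tf.principal_dir[..., None, :].copy()
        amps = tf.fa[..., None].copy()
        return cls(directions=dirs, amplitudes=amps, affine=tf.affine)


@dataclass
class StreamlineSet:
    """Retained streamlines (ordered mm points at fixed step) plus metadata."""

    streamlines: list                # list of (n_i, 3) arrays
    seeds: np.ndarray                # (n_seeds, 3) mm
    seed_indices: np.ndarray         # (n_retained,) index into seeds
    rng_seed: int
    parameters: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths(self) -> np.ndarray:
        return np.array([
            np.linalg.norm(np.diff(s, axis=0), axis=1).sum()
            for s in self.streamlines])


@dataclass
class BundleRule:
    label: str
    include: list   # list of groups; each group: list of mask names (OR within
                    # a group would be unusual here — every group must be visited)
    exclude: list = field(default_factory=list)


@dataclass
class BundleRuleSet:
    """Ordered first-match rules over named masks on a common grid."""

    rules: list                  # list of BundleRule
    masks: dict                  # name -> (X, Y, Z) bool array
    affine: np.ndarray

    def __post_init__(self):
        labels = [r.label for r in self.rules]
        if len(set(labels)) != len(labels):
            raise ValueError("bundle labels must be unique")
        shapes = {np.asarray(m).shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all masks must share one grid")
        for r in self.rules:
            for grp in r.include:
                for name in grp:
                    if name not in self.masks:
                        raise KeyError(f"unknown mask {name!r} in rule {r.label!r}")
            for name in r.exclude:
                if name not in self.masks:
                    raise KeyError(f"unknown mask {name!r} in rule {r.label!r}")


_CORNER_OFFSETS = np.array([(i, j, k) for i in (0, 1) for j in (0, 1)
                            for k in (0, 1)])


def curvature_angle_bound(step: float, radius: float) -> float:
    """Per-step turning-angle bound (radians) for a curvature radius."""
    if step >= 2 * radius:
        raise ConfigurationError(
            f"step {step} mm >= curvature diameter {2 * radius} mm")
    return 2.0 * np.arcsin(step / (2.0 * radius))


def _lookup(field: DirectionField, pos_vox: np.ndarray, ref: np.ndarray | None):
    """Trilinearly interpolated, sign-resolved direction and amplitude.

    For each of the 8 neighboring voxels the peak best aligned with the
    reference direction (sign-resolved) is selected; the weighted mean is
    normalized. With ``ref`` None the strongest peak at the nearest voxel
    seeds the alignment. Returns (direction, amplitude) or (None, 0).
    """
    shape = field.grid_shape
    base = np.floor(pos_vox).astype(int)
    frac = pos_vox - base

    if ref is None:
        nearest = np.clip(np.round(pos_vox).astype(int), 0, np.array(shape) - 1)
        peaks = field.directions[tuple(nearest)]
        amps = field.amplitudes[tuple(nearest)]
        k = int(np.argmax(amps))
        ref = peaks[k]
        if np.linalg.norm(ref) == 0:
            return None, 0.0

    corners = base + _CORNER_OFFSETS                       # (8, 3)
    wx = np.where(_CORNER_OFFSETS[:, 0] == 1, frac[0], 1 - frac[0])
    wy = np.where(_CORNER_OFFSETS[:, 1] == 1, frac[1], 1 - frac[1])
    wz = np.where(_CORNER_OFFSETS[:, 2] == 1, frac[2], 1 - frac[2])
    w = wx * wy * wz
    inside = np.all((corners >= 0) & (corners < shape), axis=1)
    w = np.where(inside, w, 0.0)
    if not np.any(w > 0):
        return None, 0.0
    ci = np.clip(corners, 0, np.array(shape) - 1)
    peaks = field.directions[ci[:, 0], ci[:, 1], ci[:, 2]]   # (8, K, 3)
    amps = field.amplitudes[ci[:, 0], ci[:, 1], ci[:, 2]]    # (8, K)
    dots = peaks @ ref                                       # (8, K)
    k = np.argmax(np.abs(dots), axis=1)
    rows = np.arange(8)
    d = peaks[rows, k] * np.where(dots[rows, k] >= 0, 1.0, -1.0)[:, None]
    acc_dir = (w[:, None] * d).sum(axis=0)
    acc_amp = float(w @ amps[rows, k])
    acc_w = float(w.sum())
    norm = np.linalg.norm(acc_dir)
    if norm == 0:
        return None, 0.0
    return acc_dir / norm, acc_amp / acc_w


def _half_track(field: DirectionField, inv_affine: np.ndarray,
                seed_world: np.ndarray, d0: np.ndarray, step: float,
                theta_max: float, cutoff: float, max_steps: int):
    """World-space points after the seed in direction d0.

    The first step follows d0 exactly so that the two half-tracks of a
    bidirectional streamline join collinearly at the seed (the discrete
    curvature bound then holds at every interior point).
    """
    pts = []
    pos = seed_world.copy()
    prev = d0.copy()
    cos_bound = np.cos(theta_max)
    hi = np.array(field.grid_shape) - 0.5
    for k in range(max_steps):
        pos_vox = pos @ inv_affine[:3, :3].T + inv_affine[:3, 3]
        if k == 0:
            d = prev
        else:
            d, amp = _lookup(field, pos_vox, prev)
            if d is None or amp < cutoff:
                break
            if np.dot(d, prev) < cos_bound - 1e-12:
                break
        nxt = pos + step * d
        nxt_vox = nxt @ inv_affine[:3, :3].T + inv_affine[:3, 3]
        if np.any(nxt_vox < -0.5) or np.any(nxt_vox > hi):
            break
        pos = nxt
        pts.append(pos.copy())
        prev = d
    return pts


def track_streamlines(field: DirectionField, seed_mask: np.ndarray,
                      n_seeds: int = 500, step: float = 0.5,
                      curvature_radius: float = 2.0,
                      min_length: float = 30.0,
                      amplitude_cutoff: float = 0.05,
                      cutoff_mode: str = "relative",
                      rng_seed: int = 0, max_steps: int = 2000,
                      seeds: np.ndarray | None = None) -> StreamlineSet:
    """Seed-and-track with the length/curvature/amplitude constraints.

    Seeds are drawn uniformly within the seed-mask voxels (reproducible
    for a fixed ``rng_seed``); explicit ``seeds`` (world mm) override the
    draw. ``cutoff_mode``: "relative" scales the cutoff by the field's
    global maximum amplitude, "absolute" uses it as-is.
    """
    seed_mask = np.asarray(seed_mask).astype(bool)
    if seed_mask.shape != field.grid_shape:
        raise ValueError("seed mask is not on the field grid")
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    if step <= 0 or min_length < 0 or curvature_radius <= 0:
        raise ConfigurationError("tracking parameters must be positive")
    theta_max = curvature_angle_bound(step, curvature_radius)

    if cutoff_mode == "relative":
        cutoff = amplitude_cutoff * float(field.amplitudes.max())
    elif cutoff_mode == "absolute":
        cutoff = amplitude_cutoff
    else:
        raise ConfigurationError(f"unknown cutoff mode {cutoff_mode!r}")

    inv_affine = np.linalg.inv(field.affine)

    if seeds is None:
        rng = np.random.default_rng(rng_seed)
        vox = np.argwhere(seed_mask)
        pick = vox[rng.integers(0, len(vox), size=n_seeds)]
        offsets = rng.uniform(-0.5, 0.5, size=(n_seeds, 3))
        seeds_world = ((pick + offsets) @ field.affine[:3, :3].T
                       + field.affine[:3, 3])
    else:
        seeds_world = np.asarray(seeds, dtype=float).reshape(-1, 3)
        n_seeds = len(seeds_world)

    streamlines, kept = [], []
    min_points = int(np.ceil(min_length / step)) + 1
    for i in range(n_seeds):
        sw = seeds_world[i]
        sv = sw @ inv_affine[:3, :3].T + inv_affine[:3, 3]
        d0, amp = _lookup(field, sv, None)
        if d0 is None or amp < cutoff:
            continue
        fwd = _half_track(field, inv_affine, sw, d0, step, theta_max,
                          cutoff, max_steps)
        bwd = _half_track(field, inv_affine, sw, -d0, step, theta_max,
                          cutoff, max_steps)
        pts = np.asarray(bwd[::-1] + [sw] + fwd)
        if len(pts) < min_points:
            continue
        streamlines.append(pts)
        kept.append(i)

    return StreamlineSet(
        streamlines=streamlines, seeds=seeds_world,
        seed_indices=np.asarray(kept, dtype=int), rng_seed=rng_seed,
        parameters=dict(step=step, curvature_radius=curvature_radius,
                        min_length=min_length,
                        amplitude_cutoff=amplitude_cutoff,
                        cutoff_mode=cutoff_mode, n_seeds=n_seeds))


def _visited_masks(points: np.ndarray, masks: dict, affine: np.ndarray,
                   grid_shape) -> set:
    ijk = containing_voxel(affine, points)
    inside = np.all((ijk >= 0) & (ijk < np.array(grid_shape)), axis=1)
    ijk = ijk[inside]
    hit = set()
    for name, m in masks.items():
        if np.any(np.asarray(m, dtype=bool)[ijk[:, 0], ijk[:, 1], ijk[:, 2]]):
            hit.add(name)
    return hit


def classify_bundles(sset: StreamlineSet, rules: BundleRuleSet) -> dict:
    """First-match labeling: every inclusion group visited, no exclusion hit.

    Returns {label: [streamline indices]} with the leftovers under
    ``"unassigned"``.
    """
    grid_shape = next(iter(rules.masks.values())).shape if rules.masks else None
    out = {r.label: [] for r in rules.rules}
    out["unassigned"] = []
    for i, pts in enumerate(sset.streamlines):
        hit = (_visited_masks(pts, rules.masks, rules.affine, grid_shape)
               if grid_shape else set())
        label = "unassigned"
        for rule in rules.rules:
            if any(name in hit for name in rule.exclude):
                continue
            if all(any(name in hit for name in grp) for grp in rule.include):
                label = rule.label
                break
        out[label].append(i)
    return out


def endpoint_density(sset: StreamlineSet, labels: np.ndarray,
                     affine: np.ndarray, indices=None) -> dict:
    """Endpoint count volumes per seed subregion.

    Each streamline is attributed to the subregion label of its seed
    voxel (nearest labeled voxel if the seed falls outside the labeled
    mask); both endpoints are accumulated. Returns
    {label: count volume}; the totals over all volumes equal twice the
    streamline count.
    """
    labels = np.asarray(labels)
    shape = labels.shape
    if indices is None:
        indices = range(len(sset.streamlines))
    present = [int(v) for v in np.unique(labels) if v != 0]
    volumes = {v: np.zeros(shape, dtype=np.int64) for v in present}

    filled = None
    for i in indices:
        pts = sset.streamlines[i]
        seed = sset.seeds[sset.seed_indices[i]]
        ijk = containing_voxel(affine, seed[None])[0]
        ijk = np.clip(ijk, 0, np.array(shape) - 1)
        lab = int(labels[tuple(ijk)])
        if lab == 0:
            if filled is None:
                from scipy.ndimage import distance_transform_edt
                _, nearest = distance_transform_edt(labels == 0,
                                                    return_indices=True)
                filled = labels[tuple(nearest)]
            lab = int(filled[tuple(ijk)])
            log.warning("seed %s outside labeled mask; attributed to "
                        "nearest label %d", np.round(seed, 1), lab)
        vol = volumes.setdefault(lab, np.zeros(shape, dtype=np.int64))
        for endpoint in (pts[0], pts[-1]):
            eijk = containing_voxel(affine, endpoint[None])[0]
            eijk = np.clip(eijk, 0, np.array(shape) - 1)
            vol[tuple(eijk)] += 1
    return volumes
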