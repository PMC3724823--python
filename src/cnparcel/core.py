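"""Core data containers shared across the pipeline.

All world coordinates are in millimetres, RAS+ following the NIfTI affine.
Diffusivities are in mm^2/s, b-values in s/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """A parameter combination that cannot produce a valid object."""


class InsufficientDataError(ValueError):
    """Not enough measurements/samples for the requested fit."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class GradientScheme:
    """Diffusion-encoding scheme: unit direction vectors and b-values.

    Zero direction vectors are permitted only for b = 0 measurements.
    """

    directions: np.ndarray  # (n, 3) unit vectors (or zero rows where b == 0)
    bvalues: np.ndarray     # (n,) s/mm^2

    def __post_init__(self):
        dirs = _as_float_array(self.directions, "directions").reshape(-1, 3)
        bvals = _as_float_array(self.bvalues, "bvalues").reshape(-1)
        if dirs.shape[0] != bvals.shape[0]:
            raise ConfigurationError(
                f"directions ({dirs.shape[0]}) and bvalues ({bvals.shape[0]}) "
                "must have the same length"
            )
        if np.any(bvals < 0):
            raise ConfigurationError("b-values must be non-negative")
        if not np.any(bvals == 0):
            raise ConfigurationError("scheme must contain at least one b=0 measurement")
        norms = np.linalg.norm(dirs, axis=1)
        nonzero_b = bvals > 0
        if np.any(norms[nonzero_b] == 0):
            raise ConfigurationError("zero direction vector with non-zero b-value")
        if np.any(np.abs(norms[nonzero_b] - 1.0) > 1e-6):
            raise ConfigurationError("direction vectors must be unit norm")
        object.__setattr__(self, "directions", dirs)
        object.__setattr__(self, "bvalues", bvals)

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvalues > 0


def fibonacci_directions(n: int) -> np.ndarray:
    """`n` well-spread unit vectors on the hemisphere (deterministic)."""
    i = np.arange(n) + 0.5
    golden = (1 + 5 ** 0.5) / 2
    phi = 2 * np.pi * i / golden
    # hemisphere: z in (0, 1)
    z = i / n
    r = np.sqrt(1 - z ** 2)
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def default_scheme(n_directions: int = 60, bvalue: float = 1000.0,
                   n_b0: int = 1) -> GradientScheme:
    """Single-shell scheme: ``n_b0`` b=0 volumes then ``n_directions`` DWIs."""
    dirs = np.vstack([np.zeros((n_b0, 3)), fibonacci_directions(n_directions)])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bvalue))])
    return GradientScheme(dirs, bvals)


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal with its scheme and voxel geometry."""

    signal: np.ndarray          # (X, Y, Z, n) >= 0
    scheme: GradientScheme
    affine: np.ndarray          # 4x4 voxel -> world (mm)
    voxel_size: tuple = field(default=None)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4D, got shape {self.signal.shape}")
        if self.signal.shape[-1] != len(self.scheme):
            raise ValueError(
                f"signal has {self.signal.shape[-1]} measurements but scheme "
                f"has {len(self.scheme)}"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal values must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if self.voxel_size is None:
            self.voxel_size = tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def shape(self):
        return self.signal.shape[:3]


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    xyz = np.asarray(xyz, dtype=float)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


def containing_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    """Index of the voxel whose center-containment cell holds each point.

    Voxel i spans [i - 0.5, i + 0.5) in voxel coordinates.
    """
    vc = world_to_voxel(affine, xyz)
    return np.floor(vc + 0.5).astype(int)
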