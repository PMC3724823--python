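"""Per-voxel diffusion-tensor fitting, FA, and direction-coded color maps."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import DWIVolume, InsufficientDataError

log = logging.getLogger(__name__)

EIGENVALUE_FLOOR = 1e-12  # mm^2/s, keeps FA defined in noisy background


@dataclass
class TensorField:
    """Fitted tensors restricted to a mask.

    ``tensors`` holds the 6 unique coefficients per masked voxel in the
    order (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz). ``principal_dir`` is
    sign-ambiguous (v and -v are equivalent).
    """

    tensors: np.ndarray        # (n_vox, 6) mm^2/s
    fa: np.ndarray             # (X, Y, Z), 0 outside mask
    principal_dir: np.ndarray  # (X, Y, Z, 3) unit vectors, 0 outside mask
    eigenvalues: np.ndarray    # (n_vox, 3) descending, clamped >= 0
    mask: np.ndarray           # (X, Y, Z) bool
    affine: np.ndarray         # 4x4

    @property
    def fa_masked(self) -> np.ndarray:
        return self.fa[self.mask]

    def dense_tensors(self) -> np.ndarray:
        """(n_vox, 3, 3) symmetric matrices."""
        t = self.tensors
        out = np.empty((len(t), 3, 3))
        out[:, 0, 0] = t[:, 0]
        out[:, 1, 1] = t[:, 1]
        out[:, 2, 2] = t[:, 2]
        out[:, 0, 1] = out[:, 1, 0] = t[:, 3]
        out[:, 0, 2] = out[:, 2, 0] = t[:, 4]
        out[:, 1, 2] = out[:, 2, 1] = t[:, 5]
        return out


def design_matrix(scheme) -> np.ndarray:
    """Log-linear design: ln S = ln S0 - b g^T D g.

    Columns: [1, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] coefficients.
    """
    g = scheme.directions
    b = scheme.bvalues
    X = np.empty((len(b), 7))
    X[:, 0] = 1.0
    X[:, 1] = -b * g[:, 0] ** 2
    X[:, 2] = -b * g[:, 1] ** 2
    X[:, 3] = -b * g[:, 2] ** 2
    X[:, 4] = -2 * b * g[:, 0] * g[:, 1]
    X[:, 5] = -2 * b * g[:, 0] * g[:, 2]
    X[:, 6] = -2 * b * g[:, 1] * g[:, 2]
    return X


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """Normalized eigenvalue dispersion, in [0, 1]."""
    ev = np.asarray(eigenvalues, dtype=float)
    mean = ev.mean(axis=-1, keepdims=True)
    num = np.sum((ev - mean) ** 2, axis=-1)
    den = np.sum(ev ** 2, axis=-1)
    fa = np.sqrt(1.5 * num / np.where(den > 0, den, 1.0))
    fa = np.where(den == 0, 0.0, fa)
    return np.clip(fa, 0.0, 1.0)


def fit_tensors(dwi: DWIVolume, mask: np.ndarray | None = None,
                signal_floor: float = 1e-8) -> TensorField:
    """Plain log-linear least-squares tensor fit per masked voxel.

    Multiple b=0 measurements are averaged into a single anatomical
    reference before fitting. Negative eigenvalues are clamped to
    ``EIGENVALUE_FLOOR``; non-positive signals are floored at
    ``signal_floor`` before the log (with a warning).
    """
    scheme = dwi.scheme
    if mask is None:
        mask = np.ones(dwi.shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != dwi.shape:
        raise ValueError("mask shape does not match DWI grid")

    dwi_sel = scheme.dwi_mask
    n_dwi = int(dwi_sel.sum())
    if n_dwi < 6:
        raise InsufficientDataError(
            f"need >= 6 diffusion-weighted directions, got {n_dwi}")
    g = scheme.directions[dwi_sel]
    # rank check on the 6 quadratic-form monomials
    q = np.stack([g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
                  g[:, 0] * g[:, 1], g[:, 0] * g[:, 2], g[:, 1] * g[:, 2]],
                 axis=1)
    if np.linalg.matrix_rank(q) < 6:
        raise InsufficientDataError("gradient directions are collinear/degenerate")

    sig = dwi.signal[mask]                               # (n_vox, n_meas)
    b0_mean = sig[:, scheme.b0_mask].mean(axis=1)
    y = np.concatenate([b0_mean[:, None], sig[:, dwi_sel]], axis=1)

    n_bad = int(np.sum(y <= 0))
    if n_bad:
        log.warning("flooring %d non-positive signal values at %g",
                    n_bad, signal_floor)
        y = np.maximum(y, signal_floor)

    from .core import GradientScheme
    fit_scheme = GradientScheme(
        np.vstack([np.zeros(3), g]),
        np.concatenate([[0.0], scheme.bvalues[dwi_sel]]))
    X = design_matrix(fit_scheme)
    coef, *_ = np.linalg.lstsq(X, np.log(y).T, rcond=None)
    coef = coef.T                                        # (n_vox, 7)
    tensors = coef[:, 1:]

    tf = TensorField(tensors=tensors,
                     fa=np.zeros(mask.shape),
                     principal_dir=np.zeros(mask.shape + (3,)),
                     eigenvalues=np.empty((len(tensors), 3)),
                     mask=mask, affine=dwi.affine)
    evals, evecs = np.linalg.eigh(tf.dense_tensors())    # ascending
    evals = np.maximum(evals, EIGENVALUE_FLOOR)
    tf.eigenvalues = evals[:, ::-1]
    tf.fa[mask] = fractional_anisotropy(evals)
    tf.principal_dir[mask] = evecs[:, :, 2]              # largest eigenvalue
    return tf


def direction_color_map(field: TensorField, scale_by_fa: bool = True
                        ) -> np.ndarray:
    """Direction-encoded RGB volume: red = left-right (|x|), green =
    posterior-anterior (|y|), blue = inferior-superior (|z|), scaled by FA.

    Sign-invariant by construction (absolute components).
    """
    if field.affine is None:
        raise ValueError("TensorField is missing its affine")
    rgb = np.abs(field.principal_dir)
    if scale_by_fa:
        rgb = rgb * field.fa[..., None]
    return np.clip(rgb, 0.0, 1.0)
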