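"""Per-voxel diffusion-tensor estimation and derived scalar maps.

The fit is ordinary least squares on the log-signal against the 6-element
tensor design plus log-S0 (exact on noiseless data). Nonpositive samples
cannot enter the log model: they are dropped per voxel, and a voxel becomes
invalid when fewer than 7 usable measurements remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionScheme, design_matrix

__all__ = ["TensorField", "DiffusivityMaps", "fit_tensor", "derive_maps"]

MIN_MEASUREMENTS = 7  # 6 tensor elements + log-S0


@dataclass
class TensorField:
    """Fitted symmetric tensors (1e-3 mm^2/s) with a per-voxel validity mask."""

    tensors: np.ndarray   # (..., 3, 3)
    valid: np.ndarray     # (...,) bool
    s0: np.ndarray        # (...,) fitted baseline signal


@dataclass
class DiffusivityMaps:
    """Axis diffusivities, FA and principal direction derived from a fit.

    Dx, Dy, Dz are the laboratory-frame diagonal tensor elements (clamped at
    zero), the quantities the perivascular-diffusivity index reads off; FA is
    computed from eigenvalues clamped at zero so it stays in [0, 1].
    """

    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray
    fa: np.ndarray
    principal_direction: np.ndarray  # (..., 3) unit vectors
    valid: np.ndarray


def _tensor_from_params(beta6: np.ndarray) -> np.ndarray:
    """Pack [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] into symmetric 3x3 arrays."""
    out = np.empty(beta6.shape[:-1] + (3, 3))
    out[..., 0, 0] = beta6[..., 0]
    out[..., 1, 1] = beta6[..., 1]
    out[..., 2, 2] = beta6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = beta6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = beta6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = beta6[..., 5]
    return out


def fit_tensor(
    stack: np.ndarray, scheme: AcquisitionScheme, mask: np.ndarray | None = None
) -> TensorField:
    """OLS log-linear tensor fit inside `mask` (everywhere if None)."""
    stack = np.asarray(stack, dtype=float)
    if stack.shape[-1] != scheme.n_volumes:
        raise ValueError(
            f"stack has {stack.shape[-1]} volumes, scheme has {scheme.n_volumes}"
        )
    spatial = stack.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    if mask.shape != spatial:
        raise ValueError("mask shape does not match stack")

    X = design_matrix(scheme)
    pinv = np.linalg.pinv(X)

    tensors = np.zeros(spatial + (3, 3))
    s0 = np.zeros(spatial)
    valid = np.zeros(spatial, dtype=bool)

    sig = stack[mask]                       # (m, n)
    ok_rows = (sig > 0).all(axis=1)

    beta_all = np.zeros((sig.shape[0], 7))
    if ok_rows.any():
        beta_all[ok_rows] = np.log(sig[ok_rows]) @ pinv.T
    row_valid = ok_rows.copy()

    # Slow path: voxels with some nonpositive samples, fitted on the usable subset.
    for i in np.flatnonzero(~ok_rows):
        use = sig[i] > 0
        if use.sum() < MIN_MEASUREMENTS:
            continue
        Xi = X[use]
        if np.linalg.matrix_rank(Xi) < 7:
            continue
        beta_all[i], *_ = np.linalg.lstsq(Xi, np.log(sig[i, use]), rcond=None)
        row_valid[i] = True

    tensors[mask] = _tensor_from_params(beta_all[:, :6])
    s0[mask] = np.exp(beta_all[:, 6])
    valid[mask] = row_valid
    return TensorField(tensors=tensors, valid=valid, s0=s0)


def derive_maps(field: TensorField) -> DiffusivityMaps:
    """Axis diffusivities (diagonal read-off), FA and principal eigenvector."""
    D = field.tensors
    evals, evecs = np.linalg.eigh(D)        # ascending eigenvalues
    lam = np.clip(evals, 0.0, None)
    mean_lam = lam.mean(axis=-1, keepdims=True)
    num = ((lam - mean_lam) ** 2).sum(axis=-1)
    den = (lam**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)

    principal = evecs[..., :, -1]
    norms = np.linalg.norm(principal, axis=-1, keepdims=True)
    principal = np.where(norms > 0, principal / np.where(norms == 0, 1, norms), principal)

    return DiffusivityMaps(
        dx=np.clip(D[..., 0, 0], 0.0, None),
        dy=np.clip(D[..., 1, 1], 0.0, None),
        dz=np.clip(D[..., 2, 2], 0.0, None),
        fa=fa,
        principal_direction=principal,
        valid=field.valid,
    )
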