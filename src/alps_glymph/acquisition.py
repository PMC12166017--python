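"""Single-shell diffusion acquisition schemes and the tensor forward model.

The scanner frame follows the RAS convention used throughout the package:
x = right-left, y = anterior-posterior, z = inferior-superior.  Diffusion
tensors are expressed in units of 1e-3 mm^2/s; b-values in s/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "InvalidSchemeError",
    "make_scheme",
    "design_matrix",
    "forward_signal",
    "write_fsl_gradients",
    "read_fsl_gradients",
]


class InvalidSchemeError(ValueError):
    """Raised when an acquisition scheme cannot support a tensor fit."""


@dataclass(frozen=True)
class AcquisitionScheme:
    """A set of diffusion weightings: one b-value and unit direction per volume.

    Parameters
    ----------
    bvalues
        Array of shape (n,), b-values in s/mm^2. At least one entry must be 0.
    directions
        Array of shape (n, 3), unit gradient directions. Directions of b=0
        entries are conventionally stored as (0, 0, 1) and never enter the
        signal model.
    """

    bvalues: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        if b.ndim != 1 or g.shape != (b.size, 3):
            raise InvalidSchemeError(
                f"shape mismatch: bvalues {b.shape}, directions {g.shape}"
            )
        if not np.any(b == 0):
            raise InvalidSchemeError("scheme needs at least one b=0 entry")
        norms = np.linalg.norm(g, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise InvalidSchemeError("all directions must have unit norm (1e-9)")
        dwi = b > 0
        if dwi.sum() < 6:
            raise InvalidSchemeError("need at least 6 diffusion-weighted entries")
        # Non-collinearity: the 6 tensor columns of the design must span R^6.
        if np.linalg.matrix_rank(design_matrix_from(b[dwi], g[dwi])[:, :6]) < 6:
            raise InvalidSchemeError("directions do not span the tensor space")
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "directions", g)

    @property
    def n_volumes(self) -> int:
        return int(self.bvalues.size)


def make_scheme(n_directions: int, b: float, seed: int) -> AcquisitionScheme:
    """Build a single-shell scheme: one b=0 plus `n_directions` at b.

    Directions are drawn approximately uniformly on the unit sphere
    (normalised Gaussian vectors), deterministically for a given seed.
    """
    if n_directions < 6:
        raise InvalidSchemeError("a tensor fit needs at least 6 directions")
    if b <= 0:
        raise InvalidSchemeError("b must be positive for the weighted shell")
    rng = np.random.default_rng(seed)
    while True:
        g = rng.standard_normal((n_directions, 3))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        if np.linalg.matrix_rank(design_matrix_from(np.full(n_directions, b), g)[:, :6]) == 6:
            break
    bvalues = np.concatenate(([0.0], np.full(n_directions, float(b))))
    directions = np.vstack(([0.0, 0.0, 1.0], g))
    return AcquisitionScheme(bvalues=bvalues, directions=directions)


def design_matrix_from(bvalues: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Log-linear tensor design for D in 1e-3 mm^2/s.

    ln S = ln S0 - 1e-3 * b * (gx^2 Dxx + gy^2 Dyy + gz^2 Dzz
                               + 2 gx gy Dxy + 2 gx gz Dxz + 2 gy gz Dyz)

    Columns: [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0].
    """
    b = np.asarray(bvalues, dtype=float)[:, None]
    gx, gy, gz = (np.asarray(directions, dtype=float)[:, i] for i in range(3))
    quad = np.column_stack(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )
    X = np.empty((b.size, 7))
    X[:, :6] = -1e-3 * b * quad
    X[:, 6] = 1.0
    return X


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    return design_matrix_from(scheme.bvalues, scheme.directions)


def forward_signal(tensor: np.ndarray, scheme: AcquisitionScheme, s0: float) -> np.ndarray:
    """Noiseless monoexponential DWI signal S = S0 exp(-b g'Dg) per scheme entry.

    `tensor` is a symmetric 3x3 array in 1e-3 mm^2/s.
    """
    D = np.asarray(tensor, dtype=float)
    if D.shape != (3, 3) or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("tensor must be a symmetric 3x3 array")
    g = scheme.directions
    quad = np.einsum("ni,ij,nj->n", g, D, g)
    return s0 * np.exp(-1e-3 * scheme.bvalues * quad)


def write_fsl_gradients(scheme: AcquisitionScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write FSL-dialect gradient tables: bval 1 row, bvec 3 rows x N columns.

    b=0 columns are written as zero vectors, following FSL convention.
    """
    b = scheme.bvalues
    g = scheme.directions.copy()
    g[b == 0] = 0.0
    Path(bval_path).write_text(" ".join(f"{v:g}" for v in b) + "\n")
    rows = [" ".join(f"{v:.6f}" for v in g[:, i]) for i in range(3)]
    Path(bvec_path).write_text("\n".join(rows) + "\n")


def read_fsl_gradients(bval_path: str | Path, bvec_path: str | Path) -> AcquisitionScheme:
    b = np.loadtxt(bval_path, ndmin=1)
    g = np.loadtxt(bvec_path, ndmin=2).T
    g = g.copy()
    zero = np.linalg.norm(g, axis=1) == 0
    g[zero & (b == 0)] = [0.0, 0.0, 1.0]
    nz = ~ (b == 0)
    norms = np.linalg.norm(g[nz], axis=1, keepdims=True)
    g[nz] = g[nz] / norms
    return AcquisitionScheme(bvalues=b, directions=g)
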