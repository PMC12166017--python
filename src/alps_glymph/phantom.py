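"""Voxelised DWI phantoms: region geometry, signal synthesis, Rician noise.

A phantom is a cubic grid partitioned into disjoint labelled regions
(projection-fiber block, association-fiber block, ventricle, WMH lesions,
background parenchyma) each carrying one ground-truth diffusion tensor.
Projection fibers run inferior-superior (z), association fibers
anterior-posterior (y), so in the scanner frame those blocks hold
diagonal-dominant tensors with the largest diagonal element on z and y
respectively.

Volumes are represented at a declared scale (`volume_scale`, default 1:100):
a mask of `n` voxels at `v` mm isotropic represents n*v^3/volume_scale
microlitres of anatomy, which lets a whole head's worth of ventricle and
intracranial volume live inside a 32-64 voxel grid while preserving every
volume ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionScheme, forward_signal

__all__ = [
    "RegionOverlapError",
    "PhantomSpec",
    "Phantom",
    "default_region_tensors",
    "cohort_geometry",
    "build_phantom",
    "add_rician_noise",
]

# Isotropic diffusivities (1e-3 mm^2/s) for non-fiber tissue classes:
# free water in the ventricles, oedematous WMH lesions, mixed parenchyma.
VENTRICLE_ADC = 3.0
WMH_ADC = 1.2
BACKGROUND_ADC = 0.8


class RegionOverlapError(ValueError):
    """Raised when two phantom regions claim the same voxel."""


@dataclass
class PhantomSpec:
    """Geometry + ground truth for one synthetic subject.

    Parameters
    ----------
    shape
        Grid shape in voxels (isotropic cube expected, any box accepted).
    voxel_size
        Edge length in mm (isotropic).
    regions
        Mapping name -> boolean mask of `shape`. Must be pairwise disjoint.
        Recognised names: "projection", "association", "ventricle", "wmh",
        "background"; "icv" is a container mask and may overlap the others.
    tensors
        Mapping name -> symmetric PSD 3x3 tensor (1e-3 mm^2/s) for every
        region in `regions`.
    s0
        Baseline (b=0) signal.
    snr
        Signal-to-noise ratio S0/sigma for Rician noise; must be > 0.
    volume_scale
        Anatomical-volume scale of the masks (mask mL = true mL * scale).
    seed
        Noise seed for this subject.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    regions: dict[str, np.ndarray]
    tensors: dict[str, np.ndarray]
    s0: float = 1000.0
    snr: float = 40.0
    volume_scale: float = 0.01
    seed: int = 0
    icv_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        occupancy = np.zeros(self.shape, dtype=np.int32)
        for name, mask in self.regions.items():
            if mask.shape != tuple(self.shape):
                raise ValueError(f"region {name!r} mask shape {mask.shape} != {self.shape}")
            occupancy += mask.astype(np.int32)
        if (occupancy > 1).any():
            raise RegionOverlapError("phantom regions overlap")
        for name in self.regions:
            D = np.asarray(self.tensors[name], dtype=float)
            if D.shape != (3, 3) or not np.allclose(D, D.T, atol=1e-10):
                raise ValueError(f"tensor for region {name!r} not symmetric 3x3")
            if np.linalg.eigvalsh(D).min() < -1e-12:
                raise ValueError(f"tensor for region {name!r} not positive semi-definite")


@dataclass
class Phantom:
    """A realised phantom: 4-D signal stack plus its ground-truth masks."""

    stack: np.ndarray                 # (nx, ny, nz, n_volumes)
    spec: PhantomSpec
    scheme: AcquisitionScheme

    @property
    def masks(self) -> dict[str, np.ndarray]:
        return self.spec.regions


def default_region_tensors(
    proj_diag: tuple[float, float, float],
    assoc_diag: tuple[float, float, float],
) -> dict[str, np.ndarray]:
    """Laboratory-frame diagonal tensors for the five tissue regions."""
    return {
        "projection": np.diag(proj_diag).astype(float),
        "association": np.diag(assoc_diag).astype(float),
        "ventricle": VENTRICLE_ADC * np.eye(3),
        "wmh": WMH_ADC * np.eye(3),
        "background": BACKGROUND_ADC * np.eye(3),
    }


def _fill_by_distance(
    allowed: np.ndarray, center: np.ndarray, count: int
) -> np.ndarray:
    """Deterministic quasi-spherical region: the `count` allowed voxels
    closest to `center` (Euclidean on voxel indices, index-order tie-break)."""
    idx = np.argwhere(allowed)
    if count > idx.shape[0]:
        raise ValueError(f"region of {count} voxels does not fit ({idx.shape[0]} available)")
    mask = np.zeros(allowed.shape, dtype=bool)
    if count == 0:
        return mask
    d2 = ((idx - center[None, :]) ** 2).sum(axis=1)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2))
    chosen = idx[order[:count]]
    mask[tuple(chosen.T)] = True
    return mask


def cohort_geometry(
    grid_n: int,
    vv_voxels: int,
    wmh_voxels: int,
    icv_voxels: int,
) -> dict[str, np.ndarray]:
    """Standard-space region masks for a cubic grid of side `grid_n`.

    The layout is a schematic left-hemisphere periventricular slab: two
    fiber blocks lateral to a ventricle region, WMH above the blocks, all
    inside a quasi-spherical intracranial mask. Coordinates scale linearly
    from a 32-voxel template so ROI template positions are grid-independent.
    """
    if grid_n < 32:
        raise ValueError("grid must be at least 32 voxels per side")
    s = grid_n / 32.0
    shape = (grid_n, grid_n, grid_n)
    c = (grid_n - 1) / 2.0
    center = np.array([c, c, c])

    def box(x0, x1, y0, y1, z0, z1):
        m = np.zeros(shape, dtype=bool)
        m[
            round(x0 * s): round(x1 * s),
            round(y0 * s): round(y1 * s),
            round(z0 * s): round(z1 * s),
        ] = True
        return m

    # Left hemisphere is low x (RAS: +x = right).
    projection = box(5, 13, 10, 18, 12, 20)
    association = box(5, 13, 18, 25, 12, 20)

    head = np.zeros(shape, dtype=bool)
    ix = np.indices(shape)
    r2 = sum((ix[i] - center[i]) ** 2 for i in range(3))
    head |= r2 <= (0.47 * grid_n) ** 2

    vent_zone = head & ~projection & ~association
    vent_zone[: round(17 * s)] = False        # keep ventricle medial/right
    ventricle = _fill_by_distance(
        vent_zone, np.array([19.5 * s, c, c]), vv_voxels
    )

    wmh_zone = head & ~projection & ~association & ~ventricle
    wmh = _fill_by_distance(
        wmh_zone, np.array([8.5 * s, 15.5 * s, 23.0 * s]), wmh_voxels
    )

    interior = projection | association | ventricle | wmh
    icv_fill = _fill_by_distance(np.ones(shape, dtype=bool), center, icv_voxels)
    icv = icv_fill | interior

    background = icv & ~interior
    return {
        "projection": projection,
        "association": association,
        "ventricle": ventricle,
        "wmh": wmh,
        "background": background,
        "icv": icv,
    }


def roi_template_centers(grid_n: int) -> dict[str, np.ndarray]:
    """Template ROI centers (voxel coordinates) at the fiber-block centroids."""
    s = grid_n / 32.0
    return {
        "projection": np.array([8.5, 13.5, 15.5]) * s,
        "association": np.array([8.5, 21.0, 15.5]) * s,
    }


def build_phantom(spec: PhantomSpec, scheme: AcquisitionScheme) -> Phantom:
    """Synthesise the noiseless 4-D DWI stack for `spec`.

    Each region is homogeneous, so the stack is assembled by broadcasting one
    forward-model signal vector per region; voxels outside all regions stay 0.
    """
    stack = np.zeros(tuple(spec.shape) + (scheme.n_volumes,), dtype=float)
    for name, mask in spec.regions.items():
        sig = forward_signal(spec.tensors[name], scheme, spec.s0)
        stack[mask] = sig
    return Phantom(stack=stack, spec=spec, scheme=scheme)


def add_rician_noise(
    stack: np.ndarray, snr: float, seed: int | np.random.Generator, s0: float = 1000.0
) -> np.ndarray:
    """Rician (magnitude-MRI) noise: sqrt((S + n1)^2 + n2^2).

    n1, n2 are iid zero-mean Gaussian with SD sigma = s0/snr; reproducible
    for a fixed integer seed.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = s0 / snr
    n1 = rng.standard_normal(stack.shape)
    n2 = rng.standard_normal(stack.shape)
    return np.sqrt((stack + sigma * n1) ** 2 + (sigma * n2) ** 2)
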