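"""The perivascular-diffusivity (ALPS) index.

At the level of the lateral-ventricle body the perivascular space runs
right-left (x), perpendicular both to projection fibers (inferior-superior,
z) and association fibers (anterior-posterior, y).  Diffusivity along x in
those two fiber regions therefore carries the perivascular component, and
the index

    ALPS = (Dx_proj + Dx_assoc) / (Dy_proj + Dz_assoc)

compares it against diffusivities perpendicular to both the fibers and the
perivascular space.  Values near 1.0 mean no perivascular-direction excess;
higher values mean freer diffusion along the perivascular space.

Measurements use 5-mm-diameter spherical ROIs in the left hemisphere, one
per fiber region; two simulated readers place the ROIs independently (their
jitter models manual placement variability) and their diffusivities are
averaged before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .tensor import DiffusivityMaps

__all__ = [
    "ROISpec",
    "ALPSResult",
    "sphere_mask",
    "roi_mean",
    "compute_alps",
    "subject_alps",
    "average_readers",
]

DIFFUSIVITY_KEYS = ("dx_proj", "dx_assoc", "dy_proj", "dy_assoc", "dz_proj", "dz_assoc")


@dataclass(frozen=True)
class ROISpec:
    """A spherical region of interest in voxel coordinates.

    `center` is 0-based voxel coordinates (fractional allowed), `diameter`
    in mm. The hemisphere tag records the measurement convention (left only).
    """

    label: str                     # "projection" | "association"
    center: tuple[float, float, float]
    diameter: float = 5.0
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        if self.label not in ("projection", "association"):
            raise ValueError(f"unknown ROI label {self.label!r}")
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be > 0")


@dataclass(frozen=True)
class ALPSResult:
    """Six ROI-mean diffusivities (1e-3 mm^2/s) and the index, per reader."""

    dx_proj: float
    dx_assoc: float
    dy_proj: float
    dy_assoc: float
    dz_proj: float
    dz_assoc: float
    alps_index: float
    reader: int

    def diffusivities(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in DIFFUSIVITY_KEYS}


def sphere_mask(
    roi: ROISpec, voxel_size: float, grid: tuple[int, int, int]
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within diameter/2 of the ROI
    center (distances in mm; inclusive boundary)."""
    center = np.asarray(roi.center, dtype=float)
    if (center < 0).any() or (center > np.asarray(grid) - 1).any():
        raise ValueError(f"ROI center {tuple(center)} outside grid {grid}")
    radius_vox = (roi.diameter / 2.0) / voxel_size
    lo = np.maximum(np.floor(center - radius_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius_vox).astype(int) + 1, grid)
    mask = np.zeros(grid, dtype=bool)
    sub = np.indices(tuple(hi - lo))
    d2 = sum((sub[i] + lo[i] - center[i]) ** 2 for i in range(3))
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = d2 <= radius_vox**2 + 1e-12
    if not mask.any():
        raise ValueError("sphere ROI contains no voxel centers")
    return mask


def roi_mean(
    scalar_map: np.ndarray, voxels: np.ndarray, valid: np.ndarray | None = None
) -> tuple[float, float]:
    """Mean of `scalar_map` over the ROI's valid voxels.

    Returns (mean, invalid_fraction); raises if every ROI voxel is invalid.
    """
    if not voxels.any():
        raise ValueError("empty voxel set")
    if valid is None:
        valid = np.ones(scalar_map.shape, dtype=bool)
    use = voxels & valid
    n_total = int(voxels.sum())
    n_use = int(use.sum())
    if n_use == 0:
        raise ValueError("all ROI voxels are invalid")
    return float(scalar_map[use].mean()), 1.0 - n_use / n_total


def compute_alps(dx_proj: float, dx_assoc: float, dy_proj: float, dz_assoc: float) -> float:
    """(Dx_proj + Dx_assoc) / (Dy_proj + Dz_assoc)."""
    den = dy_proj + dz_assoc
    if den <= 0:
        raise ValueError("nonpositive denominator in ALPS index")
    return (dx_proj + dx_assoc) / den


def _jitter_center(
    center: np.ndarray, jitter_mm: float, voxel_size: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform displacement within a ball of radius `jitter_mm`."""
    if jitter_mm == 0:
        return center
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    radius = jitter_mm * rng.random() ** (1.0 / 3.0)
    return center + direction * radius / voxel_size


def _measure(maps: DiffusivityMaps, proj_roi: ROISpec, assoc_roi: ROISpec,
             voxel_size: float, reader: int) -> ALPSResult:
    grid = maps.dx.shape
    proj_vox = sphere_mask(proj_roi, voxel_size, grid)
    assoc_vox = sphere_mask(assoc_roi, voxel_size, grid)
    vals = {}
    for axis, m in (("dx", maps.dx), ("dy", maps.dy), ("dz", maps.dz)):
        vals[f"{axis}_proj"], _ = roi_mean(m, proj_vox, maps.valid)
        vals[f"{axis}_assoc"], _ = roi_mean(m, assoc_vox, maps.valid)
    index = compute_alps(vals["dx_proj"], vals["dx_assoc"], vals["dy_proj"], vals["dz_assoc"])
    return ALPSResult(alps_index=index, reader=reader, **vals)


def subject_alps(
    maps: DiffusivityMaps,
    proj_roi: ROISpec,
    assoc_roi: ROISpec,
    voxel_size: float = 1.0,
    reader_jitter: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[ALPSResult, ALPSResult]:
    """Measure the index for two simulated readers.

    Each reader independently displaces both ROI centers by a uniform random
    offset of magnitude <= `reader_jitter` mm. With jitter 0 the readers
    coincide exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    results = []
    for reader in (1, 2):
        proj = replace(
            proj_roi,
            center=tuple(
                _jitter_center(np.asarray(proj_roi.center), reader_jitter, voxel_size, rng)
            ),
        )
        assoc = replace(
            assoc_roi,
            center=tuple(
                _jitter_center(np.asarray(assoc_roi.center), reader_jitter, voxel_size, rng)
            ),
        )
        results.append(_measure(maps, proj, assoc, voxel_size, reader))
    return results[0], results[1]


def average_readers(a: ALPSResult, b: ALPSResult) -> tuple[ALPSResult, float]:
    """Average the two readers' measurements for one subject.

    The six diffusivities are averaged component-wise and the index is
    recomputed from the averaged diffusivities; the mean of the two
    per-reader indexes is returned alongside for comparison (the order of
    averaging and division does not commute in general).
    """
    if a.reader == b.reader:
        raise ValueError("reader ids must differ")
    means = {k: 0.5 * (getattr(a, k) + getattr(b, k)) for k in DIFFUSIVITY_KEYS}
    index = compute_alps(
        means["dx_proj"], means["dx_assoc"], means["dy_proj"], means["dz_assoc"]
    )
    averaged = ALPSResult(alps_index=index, reader=0, **means)
    return averaged, 0.5 * (a.alps_index + b.alps_index)
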