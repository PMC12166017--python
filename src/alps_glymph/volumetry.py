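"""Mask-based volumetry: ventricular, intracranial and lesion volumes.

Volumes are voxel count x voxel volume; ICV normalisation expresses the
ventricular (VV) and white-matter-hyperintensity (WMH) volumes as
percentages of intracranial volume, removing head-size variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["VolumeReport", "mask_volume", "normalise_volume", "volume_report"]


@dataclass(frozen=True)
class VolumeReport:
    """Volumes in mL, normalised volumes in % of ICV, Fazekas grades 0-3."""

    vv_ml: float
    icv_ml: float
    wmhv_ml: float
    vv_icv_pct: float
    wmhv_icv_pct: float
    pwmh_grade: int
    dwmh_grade: int

    def __post_init__(self) -> None:
        if self.vv_ml > self.icv_ml or self.wmhv_ml > self.icv_ml:
            raise ValueError("VV and WMHv cannot exceed ICV")
        for g in (self.pwmh_grade, self.dwmh_grade):
            if g not in (0, 1, 2, 3):
                raise ValueError("Fazekas grades are integers 0-3")


def mask_volume(mask: np.ndarray, voxel_size: float) -> float:
    """Volume of a binary mask in mL (voxel count x voxel volume)."""
    n = int(np.count_nonzero(mask))
    if n == 0:
        warnings.warn("empty mask: volume 0 mL", stacklevel=2)
    return n * float(voxel_size) ** 3 / 1000.0


def normalise_volume(vol_ml: float, icv_ml: float) -> float:
    """Volume as a percentage of intracranial volume."""
    if icv_ml <= 0:
        raise ValueError("ICV must be positive")
    return 100.0 * vol_ml / icv_ml


def volume_report(
    ventricle_mask: np.ndarray,
    icv_mask: np.ndarray,
    wmh_mask: np.ndarray,
    voxel_size: float,
    pwmh_grade: int,
    dwmh_grade: int,
    volume_scale: float = 1.0,
) -> VolumeReport:
    """Measure all volumes from masks and normalise by ICV.

    `volume_scale` converts mask volumes (which may be stored at a reduced
    anatomical scale) back to true millilitres.
    """
    vv = mask_volume(ventricle_mask, voxel_size) / volume_scale
    icv = mask_volume(icv_mask, voxel_size) / volume_scale
    wmhv = mask_volume(wmh_mask, voxel_size) / volume_scale
    return VolumeReport(
        vv_ml=vv,
        icv_ml=icv,
        wmhv_ml=wmhv,
        vv_icv_pct=normalise_volume(vv, icv),
        wmhv_icv_pct=normalise_volume(wmhv, icv),
        pwmh_grade=pwmh_grade,
        dwmh_grade=dwmh_grade,
    )
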