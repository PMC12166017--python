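"""NIfTI and table IO helpers (RAS affine, isotropic voxels)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def write_nifti(path: str | Path, data: np.ndarray, voxel_size: float) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel_size = float(img.header.get_zooms()[0])
    return np.asarray(img.dataobj), voxel_size


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
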