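"""Volume and table I/O.

Volumes travel as NIfTI (via nibabel) with the voxel size recorded in the
affine; density matrices and cell tables as CSV with empty strings for
N/A (distinct from literal zeros)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .densities import DensityAtlas, NisslVolume
from .ontology import AnnotationVolume

__all__ = [
    "save_volume",
    "load_annotation",
    "load_intensity",
    "save_density_matrix",
    "load_density_matrix",
]


def save_volume(grid: np.ndarray, voxel_size_um: float, path: str | Path) -> None:
    affine = np.diag([voxel_size_um / 1000.0] * 3 + [1.0])  # mm units
    nib.save(nib.Nifti1Image(np.asarray(grid), affine), str(path))


def _load(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel_mm = float(img.affine[0, 0])
    return np.asarray(img.dataobj), voxel_mm * 1000.0


def load_annotation(path: str | Path) -> AnnotationVolume:
    grid, vx = _load(path)
    return AnnotationVolume(grid=grid.astype(np.int32), voxel_size_um=vx)


def load_intensity(path: str | Path) -> NisslVolume:
    grid, vx = _load(path)
    return NisslVolume(grid=grid.astype(float), voxel_size_um=vx)


def save_density_matrix(atlas: DensityAtlas, path: str | Path) -> None:
    atlas.densities.to_csv(path, na_rep="", index_label="region_id")


def load_density_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="region_id")
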