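"""NIfTI / TSV / motion-parameter serialization helpers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import BoldImage

__all__ = [
    "save_nifti",
    "load_nifti",
    "bold_to_nifti",
    "save_motion",
    "load_motion",
    "save_table",
    "load_table",
]


def _affine(voxel_size: float, shape) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    aff[:3, 3] = -voxel_size * (np.asarray(shape[:3]) - 1) / 2.0
    return aff


def bold_to_nifti(bold: BoldImage) -> nib.Nifti1Image:
    img = nib.Nifti1Image(
        np.asarray(bold.data, dtype=np.float32), _affine(bold.voxel_size, bold.data.shape)
    )
    img.header.set_zooms((bold.voxel_size,) * 3 + (bold.tr,))
    return img


def save_nifti(
    data: np.ndarray, voxel_size: float, path: str | Path, tr: float | None = None
) -> None:
    img = nib.Nifti1Image(
        np.asarray(data, dtype=np.float32), _affine(voxel_size, data.shape)
    )
    if tr is not None and data.ndim == 4:
        img.header.set_zooms((voxel_size,) * 3 + (tr,))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_motion(motion: np.ndarray, path: str | Path) -> None:
    """Six-column whitespace-delimited text, one row per timepoint."""
    np.savetxt(str(path), np.asarray(motion), fmt="%.8f")


def load_motion(path: str | Path) -> np.ndarray:
    m = np.loadtxt(str(path))
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion file must have 6 columns")
    return m


def save_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(str(path), sep="\t", index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")
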