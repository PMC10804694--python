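"""File readers/writers: NIfTI volumes, FSL bval/bvec text, per-volume transforms.

Only the FSL gradient dialect is accepted (bvec = 3 rows x N columns);
``transposed=True`` accepts the N x 3 variant. Transforms are one 4x4
whitespace-separated text matrix per volume (world-to-world, volume -> b0).
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import FormatError, GradientTable, LabelVolume, Volume3D, Volume4D

__all__ = [
    "read_dwi",
    "read_gradient_table",
    "write_gradient_table",
    "load_volume3d",
    "load_volume4d",
    "save_volume",
    "load_labels",
    "read_transforms",
    "write_transforms",
]


def read_gradient_table(path_bval, path_bvec, transposed: bool = False) -> GradientTable:
    """Read FSL-dialect bval/bvec text files into a validated GradientTable."""
    bvals = np.loadtxt(path_bval, dtype=float).ravel()
    bvecs = np.atleast_2d(np.loadtxt(path_bvec, dtype=float))
    if transposed:
        bvecs = bvecs.T
    if bvecs.shape[0] != 3:
        raise FormatError(
            f"FSL bvec files have 3 rows x N columns; got {bvecs.shape} "
            "(pass transposed=True for the N x 3 dialect)"
        )
    return GradientTable(bvals=bvals, bvecs=bvecs.T)


def write_gradient_table(gtab: GradientTable, path_bval, path_bvec) -> None:
    np.savetxt(path_bval, gtab.bvals[None, :], fmt="%.6g")
    np.savetxt(path_bvec, gtab.bvecs.T, fmt="%.10g")


def read_dwi(path_image, path_bval, path_bvec, transposed: bool = False):
    """Read a 4-D DWI NIfTI plus its FSL gradient scheme.

    Returns
    -------
    (Volume4D, GradientTable)
        Validated pair: direction norms checked, 4th-axis length checked
        against the table.
    """
    for p in (path_image, path_bval, path_bvec):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    dwi = Volume4D.from_nifti(nib.load(str(path_image)))
    gtab = read_gradient_table(path_bval, path_bvec, transposed=transposed)
    dwi.check_gradient_table(gtab)
    return dwi, gtab


def load_volume3d(path) -> Volume3D:
    return Volume3D.from_nifti(nib.load(str(path)))


def load_volume4d(path) -> Volume4D:
    return Volume4D.from_nifti(nib.load(str(path)))


def save_volume(vol: Volume3D | Volume4D, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(vol.to_nifti(), str(path))


def load_labels(path, label_names: dict[int, str]) -> LabelVolume:
    img = nib.load(str(path))
    return LabelVolume(
        np.round(np.asanyarray(img.dataobj)).astype(np.int32),
        label_names,
        np.asarray(img.affine),
    )


def read_transforms(path) -> np.ndarray:
    """Read a stack of per-volume 4x4 affines from one text file (4N x 4)."""
    flat = np.loadtxt(path, dtype=float)
    if flat.ndim != 2 or flat.shape[1] != 4 or flat.shape[0] % 4 != 0:
        raise FormatError(
            f"transform file must be (4*N) x 4 whitespace text; got {flat.shape}"
        )
    return flat.reshape(-1, 4, 4)


def write_transforms(transforms: np.ndarray, path) -> None:
    transforms = np.asarray(transforms, dtype=float)
    if transforms.ndim != 3 or transforms.shape[1:] != (4, 4):
        raise FormatError(f"expected (N, 4, 4) transforms; got {transforms.shape}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, transforms.reshape(-1, 4), fmt="%.12g")
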