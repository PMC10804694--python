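"""Shared volumetric data model: diffusion sampling schemes and NIfTI-backed volumes.

The pipeline operates in a single voxel grid per subject (all masks and label
volumes must share the grid of the image they annotate; registration is out of
scope). Voxel indices are 0-based and affines map voxel index -> world mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "Volume3D",
    "Volume4D",
    "LabelVolume",
    "ValidationError",
    "FormatError",
]

#: Free-water (isotropic compartment) diffusivity at body temperature, mm^2/s.
D_WATER = 3.0e-3


class ValidationError(ValueError):
    """A value violates a domain invariant (bad inputs, not bad files)."""


class FormatError(ValueError):
    """A file or array is structurally malformed."""


@dataclass(frozen=True)
class GradientTable:
    """Diffusion sampling scheme: per-volume b-value and unit gradient direction.

    Parameters
    ----------
    bvals : (N,) array, s/mm^2
    bvecs : (N, 3) array, unit vectors for b > 0; b = 0 rows may be zero.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (N, 3); got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise FormatError(
                f"bvals ({len(bvals)}) and bvecs ({len(bvecs)}) differ in length"
            )
        if len(bvals) < 2:
            raise ValidationError("a gradient table needs at least 2 volumes")
        if np.any(bvals < 0):
            raise ValidationError("negative b-values")
        if not np.any(bvals == 0):
            raise ValidationError("at least one b = 0 volume is required")
        norms = np.linalg.norm(bvecs[bvals > 0], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValidationError(
                "every b > 0 direction must be unit length (tol 1e-6); "
                f"worst deviation {np.abs(norms - 1.0).max():.2e}"
            )

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    def shell_bvalue(self) -> float:
        """The unique nonzero b-value; error if the scheme is multi-shell."""
        shells = np.unique(self.bvals[self.bvals > 0])
        if len(shells) != 1:
            raise ValidationError(
                f"expected a single-shell scheme, found shells {shells}"
            )
        return float(shells[0])


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise FormatError(f"affine must be 4x4; got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValidationError("affine is singular")
    return affine


@dataclass
class Volume3D:
    """A 3-D scalar volume with a voxel-to-world (RAS mm) affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected 3-D data, got shape {self.data.shape}")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "Volume3D | Volume4D") -> bool:
        return self.shape[:3] == other.shape[:3] and np.allclose(
            self.affine, other.affine
        )

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "Volume3D":
        return cls(np.asanyarray(img.dataobj), np.asarray(img.affine))


@dataclass
class Volume4D:
    """A 4-D volume (x, y, z, volume index), e.g. a DWI series."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise FormatError(f"expected 4-D data, got shape {self.data.shape}")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def volume(self, i: int) -> Volume3D:
        return Volume3D(self.data[..., i], self.affine)

    def check_gradient_table(self, gtab: GradientTable) -> None:
        if self.n_volumes != len(gtab):
            raise FormatError(
                f"image has {self.n_volumes} volumes but gradient table "
                f"has {len(gtab)} entries"
            )

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "Volume4D":
        return cls(np.asanyarray(img.dataobj), np.asarray(img.affine))


@dataclass
class LabelVolume:
    """Integer ROI labels on a grid; label 0 is background."""

    data: np.ndarray
    label_names: dict[int, str]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected 3-D labels, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise FormatError("label volume must contain integers")
            self.data = np.round(self.data).astype(np.int32)
        self.affine = _check_affine(self.affine)
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise ValidationError(f"labels without names: {sorted(missing)}")

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def mask(self, label: int) -> np.ndarray:
        return self.data == label
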