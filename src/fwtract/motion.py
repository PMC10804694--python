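"""Head-motion quantification, participant exclusion, and b-vector rotation.

Per-volume motion is summarized relative to the b0 reference frame as the RMS
over intracerebral voxels of the world-space displacement the volume's rigid/
affine transform induces. A volume is flagged when its RMS exceeds 2 mm
(strict) and a participant is excluded when more than 25% (strict) of their
diffusion-weighted volumes are flagged. Gradient directions are rotated by
the rotation component (polar decomposition) of each volume's transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import polar

from .core import GradientTable, ValidationError, Volume3D
from .stats import ancova_2x2

__all__ = [
    "MotionSummary",
    "volume_rms_displacement",
    "summarize_motion",
    "apply_exclusion",
    "rotate_bvecs",
    "motion_group_test",
]


@dataclass
class MotionSummary:
    """Per-volume RMS displacements (mm) for one subject's DWI series."""

    per_volume_rms: np.ndarray
    flag_mm: float = 2.0

    def __post_init__(self):
        self.per_volume_rms = np.asarray(self.per_volume_rms, dtype=float)
        if self.per_volume_rms.size == 0:
            raise ValidationError("empty motion summary")

    @property
    def flags(self) -> np.ndarray:
        return self.per_volume_rms > self.flag_mm  # strict

    @property
    def fraction_flagged(self) -> float:
        return float(self.flags.mean())

    @property
    def subject_mean_rms(self) -> float:
        return float(self.per_volume_rms.mean())


def volume_rms_displacement(
    transform: np.ndarray,
    mask: Volume3D,
    stride: int = 1,
) -> float:
    """RMS world-space displacement over brain-mask voxels for one volume.

    For each voxel with world coordinate x (mm), the displacement is
    ||T x - x||; the summary is sqrt(mean of squared displacements). T maps
    the volume into the b0 frame. ``stride`` subsamples mask voxels for
    speed; the default uses every intracerebral voxel.
    """
    T = np.asarray(transform, dtype=float)
    if T.shape != (4, 4):
        raise ValidationError("transform must be 4x4")
    if abs(np.linalg.det(T)) < 1e-12:
        raise ValidationError("singular transform")
    ijk = np.argwhere(np.asarray(mask.data, dtype=bool))
    if len(ijk) == 0:
        raise ValidationError("empty brain mask")
    ijk = ijk[::stride]
    xyz = ijk @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    moved = xyz @ T[:3, :3].T + T[:3, 3]
    disp2 = np.sum((moved - xyz) ** 2, axis=1)
    return float(np.sqrt(disp2.mean()))


def summarize_motion(
    transforms: np.ndarray,
    mask: Volume3D,
    gtab: GradientTable | None = None,
    flag_mm: float = 2.0,
    stride: int = 1,
) -> MotionSummary:
    """Motion summary over the diffusion-weighted volumes of a series.

    ``transforms`` holds one 4x4 affine per volume of the series. When a
    gradient table is given, b0 volumes are dropped (the b0 is the reference
    and contributes zero displacement by construction); otherwise every
    transform is treated as diffusion-weighted.
    """
    transforms = np.asarray(transforms, dtype=float)
    if gtab is not None:
        if len(transforms) != len(gtab):
            raise ValidationError("need one transform per volume")
        transforms = transforms[gtab.dwi_mask]
    rms = np.array([volume_rms_displacement(t, mask, stride=stride) for t in transforms])
    return MotionSummary(per_volume_rms=rms, flag_mm=flag_mm)


def apply_exclusion(
    summary: MotionSummary,
    flag_mm: float = 2.0,
    max_fraction: float = 0.25,
) -> str:
    """Participant-level decision: 'exclude' iff more than ``max_fraction`` of
    diffusion-weighted volumes exceed ``flag_mm`` RMS motion (both strict)."""
    if flag_mm <= 0 or max_fraction < 0:
        raise ValidationError("thresholds must be positive")
    flagged = summary.per_volume_rms > flag_mm
    return "exclude" if flagged.mean() > max_fraction else "retain"


def rotate_bvecs(scheme: GradientTable, transforms: np.ndarray) -> GradientTable:
    """Rotate each nonzero gradient direction by the rotation component of its
    volume's transform (polar decomposition of the upper-left 3x3), then
    re-normalize. b = 0 rows pass through unchanged. A reflection in the
    rotation component is rejected."""
    transforms = np.asarray(transforms, dtype=float)
    if len(transforms) != len(scheme):
        raise ValidationError("need one transform per volume")
    bvecs = scheme.bvecs.copy()
    for i, T in enumerate(transforms):
        if scheme.bvals[i] == 0:
            continue
        R, _ = polar(T[:3, :3])
        if np.linalg.det(R) < 0:
            raise ValidationError(f"transform {i} contains a reflection")
        v = R @ bvecs[i]
        bvecs[i] = v / np.linalg.norm(v)
    return GradientTable(bvals=scheme.bvals.copy(), bvecs=bvecs)


def motion_group_test(
    cohort: pd.DataFrame,
    column: str = "motion_mean_rms",
    covariates=("age_months", "scanner"),
) -> pd.DataFrame:
    """Diagnosis x sex ANCOVA on per-subject mean RMS motion (the check that
    residual head motion does not differ between groups)."""
    return ancova_2x2(cohort, column, covariates=covariates)
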