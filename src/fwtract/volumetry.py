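"""ROI volumetry: absolute volumes and percent of total brain volume.

Each ROI's voxel count times the voxel volume gives roi_mm3; total brain
volume (TBV) is the brain-mask volume on the same grid, and percent-TBV is
stored on the 0-100 scale. The group analysis runs the diagnosis x sex
ANCOVA per ROI with age and scanner covariates (percent mode) or age,
scanner and TBV (absolute mode), FDR-corrected across ROIs per effect.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .core import LabelVolume, ValidationError, Volume3D
from .stats import ancova_battery

__all__ = ["roi_volumes", "volume_group_analysis"]


def roi_volumes(
    labels: LabelVolume,
    brain_mask: Volume3D,
    subject_id: str = "subject",
) -> pd.DataFrame:
    """Per-ROI volume rows for one subject.

    Returns a DataFrame with columns subject_id, roi, roi_mm3, tbv_mm3,
    pct_tbv, empty_flag. ROI voxels falling outside the brain mask raise a
    warning with the count (they still contribute to roi_mm3); an empty ROI
    yields a zero row with ``empty_flag=True``.
    """
    if labels.shape != brain_mask.shape or not np.allclose(
        labels.affine, brain_mask.affine
    ):
        raise ValidationError("labels and brain mask must share one voxel grid")
    bmask = np.asarray(brain_mask.data, bool)
    vox = labels.voxel_volume_mm3
    tbv = float(bmask.sum()) * vox
    if tbv == 0:
        raise ValidationError("empty brain mask")
    rows = []
    for label, name in sorted(labels.label_names.items()):
        roi = labels.data == label
        n = int(roi.sum())
        outside = int((roi & ~bmask).sum())
        if outside:
            warnings.warn(
                f"ROI {name!r}: {outside} voxels outside the brain mask",
                stacklevel=2,
            )
        roi_mm3 = n * vox
        rows.append(
            dict(subject_id=subject_id, roi=name, roi_mm3=roi_mm3, tbv_mm3=tbv,
                 pct_tbv=100.0 * roi_mm3 / tbv, empty_flag=n == 0)
        )
    return pd.DataFrame(rows)


def volume_group_analysis(
    cohort: pd.DataFrame,
    roi_columns: Sequence[str],
    mode: str = "percent",
    tbv_column: str = "tbv_mm3",
) -> pd.DataFrame:
    """Diagnosis x sex ANCOVA per ROI volume column with per-effect FDR.

    ``mode='percent'`` covaries age and scanner; ``mode='absolute'``
    additionally covaries total brain volume (requires ``tbv_column``).
    """
    if mode == "percent":
        covariates = ("age_months", "scanner")
    elif mode == "absolute":
        if tbv_column not in cohort.columns:
            raise ValidationError(f"absolute mode needs a {tbv_column} column")
        covariates = ("age_months", "scanner", tbv_column)
    else:
        raise ValidationError("mode must be 'percent' or 'absolute'")
    return ancova_battery(cohort, roi_columns, covariates=covariates)
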