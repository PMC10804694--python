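"""Whole-tract and slice-level summaries of scalar maps along tract templates.

A tract template is a binary mask with a designated travel axis. Scalar maps
(tissue FA, free-water, ...) are averaged over the whole mask for the group
ANCOVA, and per slice along the travel axis for the follow-up slice-level
group comparison (pooled-variance two-sample t-tests with BH-FDR across the
slices of the tract, reported as contiguous significant runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ValidationError, Volume3D
from .stats import bh_fdr

__all__ = ["TractTemplate", "SliceProfileResult", "slice_means",
           "slice_group_test", "whole_tract_metric"]

_AXIS_NAMES = {0: "X", 1: "Y", 2: "Z"}


@dataclass
class TractTemplate:
    """A binary tract mask with a travel axis and per-slice support.

    travel_axis defaults to the axis of largest mask extent when given as
    None; slice_coords are the (0-based voxel) indices of nonempty slices.
    """

    mask: np.ndarray
    name: str = "tract"
    hemisphere: str = "L"
    travel_axis: int | None = None
    affine: np.ndarray = field(default_factory=lambda: np.diag([2.0, 2.0, 2.0, 1.0]))

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValidationError("template mask must be 3-D")
        if not self.mask.any():
            raise ValidationError("template mask is empty")
        if self.hemisphere not in ("L", "R"):
            raise ValidationError("hemisphere must be 'L' or 'R'")
        if self.travel_axis is None:
            extents = []
            for ax in range(3):
                nz = np.flatnonzero(self.mask.any(axis=tuple(a for a in range(3) if a != ax)))
                extents.append(nz[-1] - nz[0] + 1)
            self.travel_axis = int(np.argmax(extents))
        if self.travel_axis not in (0, 1, 2):
            raise ValidationError("travel_axis must be 0, 1 or 2")

    @property
    def axis_name(self) -> str:
        return _AXIS_NAMES[self.travel_axis]

    @property
    def slice_coords(self) -> np.ndarray:
        other = tuple(a for a in range(3) if a != self.travel_axis)
        return np.flatnonzero(self.mask.any(axis=other))

    def slice_voxel_counts(self) -> np.ndarray:
        other = tuple(a for a in range(3) if a != self.travel_axis)
        return self.mask.sum(axis=other)[self.slice_coords]


@dataclass
class SliceProfileResult:
    """Per-slice group comparison along one tract."""

    table: pd.DataFrame  # slice, mean/sd per group, t, p_raw, p_fdr, tested
    significant_slices: np.ndarray
    significant_runs: list[tuple[int, int]]
    alpha: float


def _check_grid(map_vol: Volume3D, template: TractTemplate) -> None:
    if map_vol.shape != template.mask.shape or not np.allclose(
        map_vol.affine, template.affine
    ):
        raise ValidationError("map and template must share one voxel grid")


def slice_means(map_vol: Volume3D, template: TractTemplate) -> pd.Series:
    """Mean of the map over template voxels, per slice along the travel axis.

    Slices whose template voxels are all null in the map get a null entry
    (excluded from downstream tests); slices outside the template support are
    omitted entirely. Indexed by 0-based slice coordinate.
    """
    _check_grid(map_vol, template)
    data = np.asarray(map_vol.data, dtype=float)
    ax = template.travel_axis
    out = {}
    for s in template.slice_coords:
        sl = [slice(None)] * 3
        sl[ax] = s
        vals = data[tuple(sl)][template.mask[tuple(sl)]]
        vals = vals[~np.isnan(vals)]
        out[int(s)] = float(vals.mean()) if len(vals) else float("nan")
    return pd.Series(out, name=f"{template.name}_{template.hemisphere}")


def whole_tract_metric(map_vol: Volume3D, template: TractTemplate) -> float:
    """Arithmetic mean of non-null map voxels over the whole template
    (equals the voxel-count-weighted mean of the slice means)."""
    _check_grid(map_vol, template)
    vals = np.asarray(map_vol.data, dtype=float)[template.mask]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValidationError("template contains no non-null voxels")
    return float(vals.mean())


def slice_group_test(
    profiles_a: pd.DataFrame | np.ndarray,
    profiles_b: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> SliceProfileResult:
    """Slice-wise two-sample t-tests between groups with BH-FDR across slices.

    ``profiles_a``/``profiles_b`` hold one row per subject and one column per
    slice (e.g. stacked outputs of :func:`slice_means`). Default is Student's
    pooled-variance test; ``equal_var=False`` switches to Welch. A slice with
    zero variance in both groups (or < 2 usable subjects in either) is skipped
    with a flag. Significant slices are those with p_FDR < alpha, also
    reported as contiguous (start, end) runs inclusive.
    """
    a = pd.DataFrame(profiles_a)
    b = pd.DataFrame(profiles_b)
    if isinstance(profiles_a, np.ndarray):
        a.columns = range(a.shape[1])
        b.columns = range(b.shape[1])
    if list(a.columns) != list(b.columns):
        raise ValidationError("group profiles cover different slices")
    rows = []
    for col in a.columns:
        xa = a[col].to_numpy(dtype=float)
        xb = b[col].to_numpy(dtype=float)
        xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
        row = dict(slice=col, n_a=len(xa), n_b=len(xb),
                   mean_a=xa.mean() if len(xa) else np.nan,
                   mean_b=xb.mean() if len(xb) else np.nan,
                   sd_a=xa.std(ddof=1) if len(xa) > 1 else np.nan,
                   sd_b=xb.std(ddof=1) if len(xb) > 1 else np.nan)
        if len(xa) < 2 or len(xb) < 2 or (np.ptp(xa) == 0 and np.ptp(xb) == 0):
            row.update(t=np.nan, p_raw=np.nan, tested=False)
        else:
            t, p = sps.ttest_ind(xa, xb, equal_var=equal_var)
            row.update(t=float(t), p_raw=float(p), tested=True)
        rows.append(row)
    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    tested = table["tested"].to_numpy()
    if tested.sum() == 0:
        raise ValidationError("no testable slices")
    table.loc[tested, "p_fdr"] = bh_fdr(table.loc[tested, "p_raw"].to_numpy())
    sig = table.loc[table["p_fdr"] < alpha, "slice"].to_numpy()
    runs = []
    for s in np.sort(sig):
        if runs and s == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], int(s))
        else:
            runs.append((int(s), int(s)))
    return SliceProfileResult(table=table, significant_slices=np.sort(sig),
                              significant_runs=runs, alpha=alpha)
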