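"""Single-shell free-water elimination and standard diffusion tensor fitting.

The signal model is the two-compartment (bi-tensor) model: a voxel's
diffusion-weighted attenuation is a mixture of an anisotropic tissue tensor
and an isotropic free-water compartment with fixed diffusivity
d_w = 3.0e-3 mm^2/s,

    S_i / S0 = (1 - f) exp(-b_i g_i' D_t g_i) + f exp(-b_i d_w).

With a single nonzero shell the inversion is ill-posed (a change in f trades
off against tissue mean diffusivity), so the fit constrains the tissue
eigenvalues to [0.1, 2.5]e-3 mm^2/s and solves the separable problem by
variable projection: for any candidate f the tissue tensor has a closed-form
weighted-least-squares solution in the log domain, so f is found by a global
1-D search (coarse grid then local refinement to ~2.5e-4 resolution) against
the signal-domain residual. An optional single smoothing pass on the f map
(discrete Laplacian step) stands in for spatial regularization;
``regularization_weight=0`` exposes the raw voxelwise fit.

The standard single-tensor fit (uncorrected FA, MD) is a weighted linear
least-squares fit of the log signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import D_WATER, GradientTable, ValidationError, Volume3D, Volume4D

__all__ = [
    "TensorField",
    "FreeWaterFit",
    "fit_dti",
    "fit_free_water",
    "fa_from_eigenvalues",
    "md_from_eigenvalues",
    "scalar_summary_in_mask",
]

#: Tissue eigenvalue box constraints, mm^2/s.
LAMBDA_MIN = 0.1e-3
LAMBDA_MAX = 2.5e-3

#: f value at and above which the tissue compartment is treated as undefined.
PURE_WATER_F = 0.99


def _design_matrix(gtab: GradientTable) -> np.ndarray:
    """(N, 7) design for ln S = ln S0 - b g' D g; columns are
    [1, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz] coefficients."""
    b = gtab.bvals
    g = gtab.bvecs
    return np.column_stack([
        np.ones(len(b)),
        -b * g[:, 0] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -b * g[:, 1] ** 2,
        -2 * b * g[:, 1] * g[:, 2],
        -b * g[:, 2] ** 2,
    ])


def _elements_to_tensors(elem: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx, Dxy, Dxz, Dyy, Dyz, Dzz] -> (..., 3, 3) symmetric."""
    D = np.empty(elem.shape[:-1] + (3, 3))
    D[..., 0, 0] = elem[..., 0]
    D[..., 0, 1] = D[..., 1, 0] = elem[..., 1]
    D[..., 0, 2] = D[..., 2, 0] = elem[..., 2]
    D[..., 1, 1] = elem[..., 3]
    D[..., 1, 2] = D[..., 2, 1] = elem[..., 4]
    D[..., 2, 2] = elem[..., 5]
    return D


def fa_from_eigenvalues(l1, l2, l3):
    """Fractional anisotropy from eigenvalues; NaN where all are zero.

    FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||.
    """
    l1, l2, l3 = np.broadcast_arrays(
        np.asarray(l1, float), np.asarray(l2, float), np.asarray(l3, float)
    )
    if np.any(np.asarray([l1, l2, l3]) < -1e-12):
        raise ValidationError("eigenvalues must be non-negative")
    mean = (l1 + l2 + l3) / 3.0
    num = (l1 - mean) ** 2 + (l2 - mean) ** 2 + (l3 - mean) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, np.nan)
    return float(fa) if fa.ndim == 0 else fa


def md_from_eigenvalues(l1, l2, l3):
    return (np.asarray(l1, float) + np.asarray(l2, float) + np.asarray(l3, float)) / 3.0


@dataclass
class TensorField:
    """Voxelwise symmetric diffusion tensors on a masked grid."""

    tensors: np.ndarray  # (X, Y, Z, 3, 3), NaN outside mask
    mask: np.ndarray
    affine: np.ndarray
    s0: Optional[np.ndarray] = None
    clamped: Optional[np.ndarray] = None  # voxels with negative eigenvalues clamped
    n_rejected: int = 0  # non-positive-signal voxels dropped from the fit

    def eigenvalues(self) -> np.ndarray:
        """(X, Y, Z, 3) eigenvalues sorted descending, clamped at 0."""
        ev = np.full(self.mask.shape + (3,), np.nan)
        vals = np.linalg.eigvalsh(self.tensors[self.mask])[:, ::-1]
        ev[self.mask] = np.clip(vals, 0.0, None)
        return ev

    def fa(self) -> Volume3D:
        ev = self.eigenvalues()
        return Volume3D(fa_from_eigenvalues(ev[..., 0], ev[..., 1], ev[..., 2]),
                        self.affine)

    def md(self) -> Volume3D:
        ev = self.eigenvalues()
        return Volume3D(md_from_eigenvalues(ev[..., 0], ev[..., 1], ev[..., 2]),
                        self.affine)


def fit_dti(
    dwi: Volume4D,
    gtab: GradientTable,
    mask: Optional[Volume3D] = None,
) -> TensorField:
    """Weighted linear least-squares single-tensor fit of the log signal.

    Weights are the squared observed signals (the standard WLS choice for
    log-linearized tensor estimation). Voxels with any non-positive signal
    are dropped from the fit and tallied in ``n_rejected``.
    """
    dwi.check_gradient_table(gtab)
    if len(gtab) < 7:
        raise ValidationError("tensor fit needs >= 7 volumes")
    m = np.ones(dwi.shape[:3], bool) if mask is None else np.asarray(mask.data, bool)
    data = np.asarray(dwi.data, float)
    sig = data[m]  # (V, N)
    ok = np.all(sig > 0, axis=1)
    n_rejected = int((~ok).sum())
    fit_mask = m.copy()
    fit_mask[m] = ok
    sig = sig[ok]
    X = _design_matrix(gtab)
    y = np.log(sig)
    w = sig**2
    XtWX = np.einsum("np,vn,nq->vpq", X, w, X, optimize=True)
    XtWy = np.einsum("np,vn,vn->vp", X, w, y, optimize=True)
    theta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    tensors = np.full(m.shape + (3, 3), np.nan)
    tensors[fit_mask] = _elements_to_tensors(theta[:, 1:])
    s0 = np.full(m.shape, np.nan)
    s0[fit_mask] = np.exp(theta[:, 0])
    raw_ev = np.linalg.eigvalsh(tensors[fit_mask])
    clamped = np.zeros(m.shape, bool)
    clamped[fit_mask] = np.any(raw_ev < 0, axis=1)
    return TensorField(tensors=tensors, mask=fit_mask, affine=dwi.affine,
                       s0=s0, clamped=clamped, n_rejected=n_rejected)


@dataclass
class FreeWaterFit:
    """Result of the single-shell bi-tensor fit."""

    fw: Volume3D                 # free-water volume fraction in [0, 1]
    tissue: TensorField          # tissue-compartment tensor (NaN where pure water)
    fa_t: Volume3D               # FA of the tissue tensor
    fa: Volume3D                 # uncorrected single-tensor FA
    md: Volume3D                 # uncorrected single-tensor MD, mm^2/s
    pure_water: np.ndarray       # voxels with f >= PURE_WATER_F (tissue undefined)
    convergence: dict = field(default_factory=dict)


def _wls_tensor_given_f(A, f, e_w, X6, XtWX_inv, WX):
    """Closed-form tissue tensors for candidate free-water fractions.

    A : (V, N) observed attenuations; f : scalar or (V,); returns
    (tensors (V, 3, 3) eigen-clamped, predicted attenuation (V, N)).
    """
    f = np.asarray(f, float)
    fcol = f[..., None] if f.ndim else f
    At = (A - fcol * e_w) / (1.0 - fcol)
    At = np.clip(At, 1e-8, 1.0)
    y = np.log(At)
    theta = np.einsum("vpq,vq->vp", XtWX_inv, np.einsum("vn,np->vp", WX * y, X6,
                                                        optimize=True))
    # theta columns: Dxx, Dxy, Dxz, Dyy, Dyz, Dzz
    D = _elements_to_tensors(theta)
    evals, evecs = np.linalg.eigh(D)
    evals = np.clip(evals, LAMBDA_MIN, LAMBDA_MAX)
    Dc = np.einsum("vik,vk,vjk->vij", evecs, evals, evecs)
    return Dc


def _predict_attenuation(Dc, f, e_w, bg_outer):
    quad = np.einsum("vij,nij->vn", Dc, bg_outer, optimize=True)
    att_t = np.exp(-quad)
    fcol = np.asarray(f, float)
    fcol = fcol[..., None] if fcol.ndim else fcol
    return (1.0 - fcol) * att_t + fcol * e_w


def fit_free_water(
    dwi: Volume4D,
    gtab: GradientTable,
    mask: Optional[Volume3D] = None,
    regularization_weight: float = 0.1,
    md_prior: float = 0.7e-3,
    md_prior_sd: Optional[float] = 0.1e-3,
    coarse_step: float = 0.01,
    fine_step: float = 2.5e-4,
) -> FreeWaterFit:
    """Fit the two-compartment free-water model to a single-shell series.

    Per voxel the signal-domain residual is minimized over f in [0, 1] and a
    tissue tensor with eigenvalues in [0.1, 2.5]e-3 mm^2/s, by variable
    projection (closed-form WLS tensor at each candidate f; global coarse
    grid in f followed by local refinement). S0 is taken from the mean b0
    signal.

    With one shell the likelihood is nearly flat along the trade-off between
    f and tissue mean diffusivity, so the selection objective is a MAP
    criterion: the signal-domain residual plus a Gaussian prior on the
    tissue-compartment MD centered at ``md_prior`` (default the canonical
    healthy white-matter value, 0.7e-3 mm^2/s) with width ``md_prior_sd``.
    The prior is scaled by the per-voxel noise variance estimated from the
    best unpenalized fit, so it vanishes on noiseless data (exact recovery)
    and resolves the degeneracy in proportion to the noise. Pass
    ``md_prior_sd=None`` for the raw maximum-likelihood fit.

    ``regularization_weight`` in [0, 1) applies one smoothing pass to the f
    map (weight 0 = raw voxelwise fit) before the tensors are refit at the
    smoothed f. Voxels whose best fit is pure water (f >= 0.99) have an
    undefined tissue tensor: FA_T is NaN there, flagged in ``pure_water``.
    """
    dwi.check_gradient_table(gtab)
    if not 0 <= regularization_weight < 1:
        raise ValidationError("regularization_weight must lie in [0, 1)")
    b = gtab.shell_bvalue()  # raises on multi-shell input
    m = np.ones(dwi.shape[:3], bool) if mask is None else np.asarray(mask.data, bool)
    if not m.any():
        raise ValidationError("empty mask")
    data = np.asarray(dwi.data, float)
    s0 = data[..., gtab.b0_mask].mean(axis=-1)
    dw_idx = gtab.dwi_mask
    fit_ok = m & (s0 > 0)
    A = data[fit_ok][:, dw_idx] / s0[fit_ok][:, None]  # (V, N) attenuations
    V = A.shape[0]
    g = gtab.bvecs[dw_idx]
    bvals = gtab.bvals[dw_idx]
    e_w = float(np.exp(-b * D_WATER))
    # design in 6 tensor elements (S0 known): ln At = -b g' D g
    X6 = _design_matrix(gtab)[dw_idx][:, 1:]
    bg_outer = bvals[:, None, None] * g[:, :, None] * g[:, None, :]  # (N, 3, 3)
    # WLS weights from the observed attenuations: fixed across candidate f,
    # which keeps the normal matrix (and its inverse) shared by all candidates
    w = np.clip(A, 1e-8, None) ** 2
    XtWX = np.einsum("np,vn,nq->vpq", X6, w, X6, optimize=True)
    XtWX_inv = np.linalg.inv(XtWX)
    WX = w  # (V, N); multiplied with y inside the solver

    def objective(f):
        Dc = _wls_tensor_given_f(A, f, e_w, X6, XtWX_inv, WX)
        pred = _predict_attenuation(Dc, f, e_w, bg_outer)
        sse = np.einsum("vn->v", (A - pred) ** 2)
        md = np.trace(Dc, axis1=-2, axis2=-1) / 3.0
        return sse, md

    # pure-water candidate (no tissue compartment)
    sse_water = ((A - e_w) ** 2).sum(axis=1)

    n_dw = A.shape[1]
    coarse = np.arange(0.0, PURE_WATER_F, coarse_step)
    coarse_sse = np.empty((len(coarse), V))
    coarse_md = np.empty((len(coarse), V))
    for k, fc in enumerate(coarse):
        coarse_sse[k], coarse_md[k] = objective(fc)
    # per-voxel noise variance from the best unpenalized fit; it scales the
    # MD prior so the penalty disappears on noiseless data
    sigma2 = np.minimum(coarse_sse.min(axis=0), sse_water) / max(n_dw - 7, 1)
    if md_prior_sd is None:
        pen = np.zeros(V)
    else:
        pen = sigma2 / (md_prior_sd**2)

    def penalized(sse, md):
        return sse + pen * (md - md_prior) ** 2

    best_obj = np.full(V, np.inf)
    best_f = np.zeros(V)
    for k, fc in enumerate(coarse):
        obj = penalized(coarse_sse[k], coarse_md[k])
        upd = obj < best_obj
        best_obj[upd] = obj[upd]
        best_f[upd] = fc
    # local refinement around the coarse winner
    center = best_f.copy()
    offsets = np.arange(-coarse_step, coarse_step + fine_step / 2, fine_step)
    for off in offsets:
        f = np.clip(center + off, 0.0, PURE_WATER_F - 1e-9)
        sse, md = objective(f)
        obj = penalized(sse, md)
        upd = obj < best_obj
        best_obj[upd] = obj[upd]
        best_f[upd] = f[upd]
    pure = sse_water < best_obj
    best_f[pure] = 1.0
    best_sse = np.where(pure, sse_water, best_obj)

    if regularization_weight > 0:
        best_f = _smooth_in_mask(best_f, fit_ok, regularization_weight)

    tissue_ok = best_f < PURE_WATER_F
    Dc_final = np.full((V, 3, 3), np.nan)
    if tissue_ok.any():
        Dc_final[tissue_ok] = _wls_tensor_given_f(
            A[tissue_ok], best_f[tissue_ok], e_w, X6,
            XtWX_inv[tissue_ok], WX[tissue_ok]
        )
    final_sse = np.where(tissue_ok, best_sse, sse_water)

    # assemble volumes
    fw_map = np.full(m.shape, np.nan)
    fw_map[fit_ok] = best_f
    tensors = np.full(m.shape + (3, 3), np.nan)
    tensors[fit_ok] = Dc_final
    tissue_mask = fit_ok.copy()
    tissue_mask[fit_ok] = tissue_ok
    tissue = TensorField(tensors=tensors, mask=tissue_mask, affine=dwi.affine)
    ev = tissue.eigenvalues()
    fa_t = Volume3D(fa_from_eigenvalues(ev[..., 0], ev[..., 1], ev[..., 2]),
                    dwi.affine)
    pure_water = fit_ok.copy()
    pure_water[fit_ok] = ~tissue_ok
    dti = fit_dti(dwi, gtab, Volume3D(fit_ok.astype(np.uint8), dwi.affine))
    obj_map = np.full(m.shape, np.nan)
    obj_map[fit_ok] = final_sse
    conv = dict(
        n_voxels=int(V),
        n_pure_water=int(pure_water.sum()),
        f_resolution=fine_step,
        mean_objective=float(final_sse.mean()),
        objective=obj_map,
        regularization_weight=regularization_weight,
    )
    return FreeWaterFit(
        fw=Volume3D(fw_map, dwi.affine),
        tissue=tissue,
        fa_t=fa_t,
        fa=dti.fa(),
        md=dti.md(),
        pure_water=pure_water,
        convergence=conv,
    )


def _smooth_in_mask(values_in_mask: np.ndarray, mask: np.ndarray, weight: float):
    """One discrete-Laplacian smoothing step of a masked scalar field:
    v <- (1 - w) v + w * mean(6-neighborhood within mask)."""
    vol = np.zeros(mask.shape)
    vol[mask] = values_in_mask
    mf = mask.astype(float)
    acc = np.zeros_like(vol)
    cnt = np.zeros_like(vol)
    for ax in range(3):
        for shift in (1, -1):
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shift == 1:
                src[ax], dst[ax] = slice(0, -1), slice(1, None)
            else:
                src[ax], dst[ax] = slice(1, None), slice(0, -1)
            acc[tuple(dst)] += (vol * mf)[tuple(src)]
            cnt[tuple(dst)] += mf[tuple(src)]
    nb_mean = np.where(cnt > 0, acc / np.maximum(cnt, 1.0), vol)
    sm = (1 - weight) * vol[mask] + weight * np.where(
        cnt[mask] > 0, nb_mean[mask], vol[mask]
    )
    return np.clip(sm, 0.0, 1.0)


def scalar_summary_in_mask(map_vol: Volume3D, mask: Volume3D) -> float:
    """Arithmetic mean of non-null map voxels inside the mask (whole-ROI /
    whole-tract averages feeding the group tables)."""
    if map_vol.shape != mask.shape or not np.allclose(map_vol.affine, mask.affine):
        raise ValidationError("map and mask must share one voxel grid")
    mbool = np.asarray(mask.data, bool)
    if not mbool.any():
        raise ValidationError("empty mask")
    vals = np.asarray(map_vol.data, float)[mbool]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValidationError("mask contains only null voxels")
    return float(vals.mean())
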