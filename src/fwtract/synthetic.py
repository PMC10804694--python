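"""Synthetic phantoms, motion traces, tract templates and cohorts.

Every downstream stage of the pipeline is exercised on data from this module,
because the study cohort it emulates (a restricted clinical archive) cannot be
redistributed. Three generators matter:

* :func:`simulate_dwi` — forward-evaluates the bi-tensor (tissue + free-water)
  signal model that the fitting stage inverts, with optional Rician noise.
* :func:`simulate_cohort` — draws subject tables whose group means/SDs equal
  configurable parameters (defaults: the published group statistics), with
  planted diagnosis/sex effects and Gaussian-copula brain-behavior links.
* :func:`simulate_motion_trace` / :func:`make_tract_template` — fixtures for
  the motion-QC rules and the along-tract profiling.

All randomness flows from explicit integer seeds; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import D_WATER, GradientTable, ValidationError, Volume4D
from .profiles import TractTemplate

__all__ = [
    "BiTensorGroundTruth",
    "CohortSpec",
    "simulate_dwi",
    "simulate_cohort",
    "simulate_motion_trace",
    "make_tract_template",
    "mirror_template",
    "eigenvalues_for_fa",
    "tensor_from_principal",
    "make_gradient_scheme",
    "demographic_cohort_spec",
    "diffusion_cohort_spec",
]


# --------------------------------------------------------------------------
# gradient scheme fixture (the acquisition the study used: 64 directions at
# b = 1000 s/mm^2 plus one b = 0 volume)

def make_gradient_scheme(n_directions: int = 64, b: float = 1000.0,
                         seed: int = 0) -> GradientTable:
    """Roughly uniform unit directions (Fibonacci sphere jittered by seed)
    preceded by a single b = 0 volume."""
    rng = np.random.default_rng(seed)
    i = np.arange(n_directions)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_directions
    r = np.sqrt(1.0 - z**2)
    theta = golden * i + rng.uniform(0, 2 * np.pi)
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([[0.0], np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros(3), dirs])
    return GradientTable(bvals=bvals, bvecs=bvecs)


# --------------------------------------------------------------------------
# bi-tensor ground truth and forward signal model

@dataclass
class BiTensorGroundTruth:
    """Voxelwise ground truth for the two-compartment signal model.

    f : free-water volume fraction in [0, 1], any array shape.
    tissue_eigenvalues : (..., 3) sorted descending, mm^2/s.
    tissue_orientation : (..., 3) principal eigenvector (need not be unit).
    S0 : non-diffusion-weighted signal, broadcastable to f.
    """

    f: np.ndarray
    tissue_eigenvalues: np.ndarray
    tissue_orientation: np.ndarray
    S0: np.ndarray

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        self.tissue_eigenvalues = np.asarray(self.tissue_eigenvalues, dtype=float)
        self.tissue_orientation = np.asarray(self.tissue_orientation, dtype=float)
        self.S0 = np.broadcast_to(np.asarray(self.S0, dtype=float), self.f.shape).copy()
        ev = self.tissue_eigenvalues
        if ev.shape[:-1] != self.f.shape or ev.shape[-1] != 3:
            raise ValidationError("tissue_eigenvalues must have shape f.shape + (3,)")
        if np.any(np.diff(ev, axis=-1) > 1e-15) or np.any(ev < 0):
            raise ValidationError("eigenvalues must satisfy l1 >= l2 >= l3 >= 0")
        if np.any((self.f < 0) | (self.f > 1)):
            raise ValidationError("f must lie in [0, 1]")
        if np.any(self.S0 <= 0):
            raise ValidationError("S0 must be positive")


def tensor_from_principal(eigenvalues: np.ndarray, e1: np.ndarray) -> np.ndarray:
    """Assemble symmetric tensors (..., 3, 3) from eigenvalues and a principal
    direction; the secondary eigenvectors span the orthogonal complement
    (their in-plane rotation is immaterial for axially symmetric tensors and
    otherwise an arbitrary but deterministic choice)."""
    ev = np.asarray(eigenvalues, dtype=float)
    e1 = np.asarray(e1, dtype=float)
    e1 = e1 / np.linalg.norm(e1, axis=-1, keepdims=True)
    helper = np.zeros_like(e1)
    # pick the cardinal axis least aligned with e1, per voxel
    idx = np.argmin(np.abs(e1), axis=-1)
    np.put_along_axis(helper, idx[..., None], 1.0, axis=-1)
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2, axis=-1, keepdims=True)
    e3 = np.cross(e1, e2)
    return (
        ev[..., 0, None, None] * e1[..., :, None] * e1[..., None, :]
        + ev[..., 1, None, None] * e2[..., :, None] * e2[..., None, :]
        + ev[..., 2, None, None] * e3[..., :, None] * e3[..., None, :]
    )


def eigenvalues_for_fa(fa: float, md: float) -> tuple[float, float, float]:
    """Axially symmetric eigenvalues (l1, l2, l2) with the given FA and MD."""
    if not 0 <= fa < 1:
        raise ValidationError("fa must lie in [0, 1)")
    if fa == 0:
        return md, md, md
    t2 = fa * fa
    r = (1.0 + np.sqrt(1.0 - (1.0 - t2) * (1.0 - 2.0 * t2))) / (1.0 - t2)
    b = 3.0 * md / (r + 2.0)
    return r * b, b, b


def simulate_dwi(
    truth: BiTensorGroundTruth,
    scheme: GradientTable,
    snr: Optional[float] = None,
    seed: int = 0,
    noise_model: str = "rician",
    affine: Optional[np.ndarray] = None,
) -> Volume4D:
    """Forward-simulate DWI signals from the two-compartment model.

    Per voxel and volume i the noiseless signal is

        S_i = S0 * [ (1 - f) exp(-b_i g_i' D_t g_i) + f exp(-b_i d_w) ]

    with D_t the tissue tensor and d_w = 3.0e-3 mm^2/s the free-water
    diffusivity. ``snr=None`` means noiseless; otherwise Rician (default) or
    Gaussian noise with sigma = S0/snr is applied independently per
    voxel/volume, driven by ``seed``.
    """
    if snr is not None and snr <= 0:
        raise ValidationError("snr must be positive (or None for noiseless)")
    if truth.f.ndim != 3:
        raise ValidationError("simulate_dwi expects a 3-D ground-truth grid")
    D = tensor_from_principal(truth.tissue_eigenvalues, truth.tissue_orientation)
    g = scheme.bvecs  # (N, 3)
    b = scheme.bvals  # (N,)
    quad = np.einsum("...ij,ni,nj->...n", D, g, g)
    att_tissue = np.exp(-b * quad)
    att_water = np.exp(-b * D_WATER)
    f = truth.f[..., None]
    signal = truth.S0[..., None] * ((1.0 - f) * att_tissue + f * att_water)
    if snr is not None:
        rng = np.random.default_rng(seed)
        sigma = truth.S0[..., None] / snr
        if noise_model == "rician":
            n1 = rng.standard_normal(signal.shape)
            n2 = rng.standard_normal(signal.shape)
            signal = np.sqrt((signal + sigma * n1) ** 2 + (sigma * n2) ** 2)
        elif noise_model == "gaussian":
            signal = signal + sigma * rng.standard_normal(signal.shape)
        else:
            raise ValidationError(f"unknown noise model {noise_model!r}")
    if affine is None:
        affine = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm isotropic acquisition
    return Volume4D(signal, affine)


# --------------------------------------------------------------------------
# tract templates

_AXES = {"X": 0, "Y": 1, "Z": 2}


def make_tract_template(
    shape: tuple[int, int, int],
    axis: str = "Y",
    extent: int = 20,
    seed: int = 0,
    name: str = "tract",
    hemisphere: str = "L",
    radius: int = 1,
    affine: Optional[np.ndarray] = None,
) -> TractTemplate:
    """A connected synthetic tract mask spanning ``extent`` slices along
    ``axis``, confined to one hemisphere (left = lower X indices). The right
    variant for the same seed is the exact mirror image across the X midline.
    """
    ax = _AXES[axis] if isinstance(axis, str) else int(axis)
    if extent < 3:
        raise ValidationError("extent must be >= 3 slices")
    if extent > shape[ax]:
        raise ValidationError(f"extent {extent} exceeds grid ({shape[ax]} slices)")
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    cross_axes = [a for a in range(3) if a != ax]
    # the tract meanders in the cross-sectional plane, staying in the left half
    half = shape[0] // 2
    lims = []
    for a in cross_axes:
        hi = (half - 1 if a == 0 else shape[a] - 1)
        lims.append((radius, hi - radius))
    pos = [rng.integers(lo, hi + 1) for lo, hi in lims]
    start = rng.integers(0, shape[ax] - extent + 1)
    for s in range(start, start + extent):
        idx = [slice(None)] * 3
        idx[ax] = s
        for a, p, (lo, hi) in zip(cross_axes, pos, lims):
            idx[a] = slice(max(p - radius, 0), min(p + radius, shape[a] - 1) + 1)
        mask[tuple(idx)] = True
        pos = [
            int(np.clip(p + rng.integers(-1, 2), lo, hi))
            for p, (lo, hi) in zip(pos, lims)
        ]
    if hemisphere == "R":
        mask = mask[::-1].copy()
    elif hemisphere != "L":
        raise ValidationError("hemisphere must be 'L' or 'R'")
    if affine is None:
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
    return TractTemplate(mask=mask, name=name, hemisphere=hemisphere,
                         travel_axis=ax, affine=affine)


def mirror_template(template: TractTemplate) -> TractTemplate:
    """Mirror a template across the X midline (left <-> right hemisphere)."""
    return TractTemplate(
        mask=template.mask[::-1].copy(),
        name=template.name,
        hemisphere="R" if template.hemisphere == "L" else "L",
        travel_axis=template.travel_axis,
        affine=template.affine,
    )


# --------------------------------------------------------------------------
# motion traces

def simulate_motion_trace(
    n_volumes: int,
    n_bad: int,
    magnitude_mm: float,
    seed: int = 0,
    jitter_mm: float = 0.5,
) -> np.ndarray:
    """Per-volume rigid transforms (volume -> b0 frame) as (N, 4, 4) affines.

    Exactly ``n_bad`` volumes receive a pure translation of Euclidean norm
    ``magnitude_mm`` in a random direction; the rest receive sub-threshold
    jitter of norm uniform in [0, jitter_mm]. Pure translations make the RMS
    displacement equal to the translation norm for any brain mask, so planted
    above-threshold volumes are recoverable exactly.
    """
    if magnitude_mm <= 0:
        raise ValidationError("magnitude_mm must be positive")
    if n_bad > n_volumes:
        raise ValidationError("n_bad cannot exceed n_volumes")
    rng = np.random.default_rng(seed)
    transforms = np.tile(np.eye(4), (n_volumes, 1, 1))
    bad = rng.choice(n_volumes, size=n_bad, replace=False)
    for v in range(n_volumes):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        norm = magnitude_mm if v in bad else rng.uniform(0, jitter_mm)
        transforms[v, :3, 3] = norm * direction
    return transforms


# --------------------------------------------------------------------------
# cohort generator

CellParams = Mapping[tuple[str, str], tuple[float, float]]


@dataclass
class CohortSpec:
    """Parameters for a synthetic cohort.

    n_per_cell : subjects per (diagnosis, sex) cell.
    metric_params : per imaging metric, either a 4-tuple
        (mean_ASD, sd_ASD, mean_TD, sd_TD) or a per-cell mapping
        {(diagnosis, sex): (mean, sd)}.
    behavior_params : same shape, for clinical scores; scores listed in
        ``integer_behaviors`` are rounded and floored at 0 after sampling
        (RBS-R-like non-normal marginals).
    behavior_link : {(metric, behavior): target Spearman rho}, realized with
        a Gaussian copula (latent Pearson r = 2 sin(pi * rho / 6)).
    age_effect / scanner_effect / sex_effect : additive shifts per metric
        (slope per month; Prisma-minus-TrioTim; male-minus-female).
    metric_corr : exchangeable correlation between metric latents.
    """

    n_per_cell: Mapping[tuple[str, str], int]
    metric_params: Mapping[str, object] = field(default_factory=dict)
    behavior_params: Mapping[str, object] = field(default_factory=dict)
    behavior_link: Mapping[tuple[str, str], float] = field(default_factory=dict)
    age_params: object = (152.0, 34.0)
    age_effect: Mapping[str, float] = field(default_factory=dict)
    scanner_effect: Mapping[str, float] = field(default_factory=dict)
    sex_effect: Mapping[str, float] = field(default_factory=dict)
    metric_corr: float = 0.0
    integer_behaviors: tuple = ()
    asd_only_behaviors: tuple = ("adir_c", "ados2")
    missing_rate: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for (m, b), rho in self.behavior_link.items():
            if abs(rho) > 1:
                raise ValidationError(f"|rho| > 1 for link ({m}, {b})")
        for params in list(self.metric_params.values()) + list(
            self.behavior_params.values()
        ):
            for sd in _all_sds(params):
                if sd <= 0:
                    raise ValidationError("all sds must be positive")
        if not (0 <= self.metric_corr < 1):
            raise ValidationError("metric_corr must lie in [0, 1)")


def _all_sds(params):
    if isinstance(params, Mapping):
        return [sd for (_, sd) in params.values()]
    return [params[1], params[3]]


def _cell_mean_sd(params, diagnosis: str, sex: str) -> tuple[float, float]:
    if isinstance(params, Mapping):
        return params[(diagnosis, sex)]
    if len(params) == 2:  # one (mean, sd) for every cell
        return tuple(params)
    mean_asd, sd_asd, mean_td, sd_td = params
    return (mean_asd, sd_asd) if diagnosis == "ASD" else (mean_td, sd_td)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a seed-deterministic cohort table from a CohortSpec.

    Metrics are cell-appropriate normals plus optional age/scanner/sex
    additive effects; behaviors are tied to their linked metrics through a
    Gaussian copula so the planted Spearman correlations hold marginally,
    then pushed through integer/floor marginal transforms where declared.
    """
    rng = np.random.default_rng(spec.seed)
    metrics = list(spec.metric_params)
    behaviors = list(spec.behavior_params)
    # copula feasibility: with independent metric latents the latent behavior
    # variable is sum(c_m z_m) + sqrt(1 - sum c^2) eps, which needs sum c^2 <= 1
    coeff: dict[str, dict[str, float]] = {b: {} for b in behaviors}
    for (m, b), rho in spec.behavior_link.items():
        if m not in metrics:
            raise ValidationError(f"behavior_link names unknown metric {m!r}")
        if b not in behaviors:
            raise ValidationError(f"behavior_link names unknown behavior {b!r}")
        coeff[b][m] = 2.0 * np.sin(np.pi * rho / 6.0)
    for b, cs in coeff.items():
        total = sum(c * c for c in cs.values())
        if total > 1.0:
            worst = max(cs, key=lambda m: abs(cs[m]))
            raise ValidationError(
                f"infeasible correlation structure: links into {b!r} imply "
                f"latent variance {total:.3f} > 1 (offending pair: ({worst}, {b}))"
            )

    rows = []
    sid = 0
    for (dx, sex), n in spec.n_per_cell.items():
        for _ in range(int(n)):
            sid += 1
            age_mean, age_sd = _cell_mean_sd(spec.age_params, dx, sex)
            age = float(np.clip(rng.normal(age_mean, age_sd), 72, 216))
            scanner = "Prisma" if rng.random() < 0.5 else "TrioTim"
            row = dict(subject_id=f"sub-{sid:04d}", diagnosis=dx, sex=sex,
                       age_months=age, scanner=scanner)
            shared = rng.standard_normal()
            z = {}
            for m in metrics:
                zm = (np.sqrt(spec.metric_corr) * shared
                      + np.sqrt(1 - spec.metric_corr) * rng.standard_normal())
                z[m] = zm
                mean, sd = _cell_mean_sd(spec.metric_params[m], dx, sex)
                val = mean + sd * zm
                val += spec.age_effect.get(m, 0.0) * (age - 152.0)
                val += spec.scanner_effect.get(m, 0.0) * (scanner == "Prisma")
                val += spec.sex_effect.get(m, 0.0) * (0.5 if sex == "M" else -0.5)
                row[m] = val
            for bname in behaviors:
                if dx == "TD" and bname in spec.asd_only_behaviors:
                    row[bname] = np.nan
                    continue
                cs = coeff[bname]
                resid = np.sqrt(max(0.0, 1.0 - sum(c * c for c in cs.values())))
                zb = sum(c * z[m] for m, c in cs.items()) + resid * rng.standard_normal()
                mean, sd = _cell_mean_sd(spec.behavior_params[bname], dx, sex)
                val = mean + sd * zb
                if bname in spec.integer_behaviors:
                    val = float(max(0, round(val)))
                if rng.random() < spec.missing_rate.get(bname, 0.0):
                    val = np.nan
                row[bname] = val
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# study-condition defaults (published group sizes, means and SDs)

#: Group mean +/- SD per (diagnosis, sex) cell for the demographic variables.
_AGE_PARAMS = {("ASD", "M"): (146.0, 35.4), ("ASD", "F"): (158.0, 31.9),
               ("TD", "M"): (161.0, 32.5), ("TD", "F"): (157.0, 38.1)}
_IQ_PARAMS = {("ASD", "M"): (102.0, 18.2), ("ASD", "F"): (102.0, 22.3),
              ("TD", "M"): (111.0, 16.2), ("TD", "F"): (109.0, 14.5)}
_RBSR_TOTAL_PARAMS = {("ASD", "M"): (23.0, 16.1), ("ASD", "F"): (19.8, 17.4),
                      ("TD", "M"): (2.24, 6.61), ("TD", "F"): (0.98, 1.77)}
_ADIR_PARAMS = {("ASD", "M"): (6.46, 2.63), ("ASD", "F"): (5.71, 2.55),
                ("TD", "M"): (0.0, 1.0), ("TD", "F"): (0.0, 1.0)}  # TD -> NaN
_SCQ_PARAMS = {("ASD", "M"): (20.4, 6.58), ("ASD", "F"): (16.4, 7.57),
               ("TD", "M"): (3.00, 3.69), ("TD", "F"): (1.77, 2.37)}

#: Whole-tract free-water-corrected FA: (mean_ASD, sd_ASD, mean_TD, sd_TD).
FA_T_PARAMS = {
    "fa_t_dlpfc_caudate_l": (0.441, 0.014, 0.450, 0.017),
    "fa_t_dlpfc_caudate_r": (0.409, 0.017, 0.415, 0.017),
    "fa_t_m1u_putamen_l": (0.403, 0.016, 0.406, 0.020),
    "fa_t_m1u_putamen_r": (0.399, 0.017, 0.401, 0.022),
    "fa_t_scp_m1u_l": (0.534, 0.014, 0.537, 0.016),
    "fa_t_scp_m1u_r": (0.520, 0.015, 0.524, 0.019),
    "fa_t_sn_putamen_l": (0.417, 0.016, 0.422, 0.018),
    "fa_t_sn_putamen_r": (0.405, 0.017, 0.409, 0.020),
    "fa_t_gpe_stn_l": (0.558, 0.019, 0.566, 0.025),
    "fa_t_gpe_stn_r": (0.573, 0.023, 0.584, 0.028),
}

#: Whole-tract free-water fraction: same layout.
FW_PARAMS = {
    "fw_dlpfc_caudate_l": (0.227, 0.028, 0.214, 0.025),
    "fw_dlpfc_caudate_r": (0.244, 0.037, 0.230, 0.032),
    "fw_m1u_putamen_l": (0.205, 0.041, 0.206, 0.052),
    "fw_m1u_putamen_r": (0.212, 0.040, 0.211, 0.047),
    "fw_scp_m1u_l": (0.184, 0.027, 0.185, 0.033),
    "fw_scp_m1u_r": (0.197, 0.031, 0.195, 0.030),
    "fw_sn_putamen_l": (0.175, 0.024, 0.164, 0.019),
    "fw_sn_putamen_r": (0.196, 0.029, 0.185, 0.027),
    "fw_gpe_stn_l": (0.156, 0.029, 0.145, 0.022),
    "fw_gpe_stn_r": (0.165, 0.030, 0.159, 0.031),
}

#: Planted brain-behavior Spearman links (the study's significant pairs).
BEHAVIOR_LINKS = {
    ("fa_t_dlpfc_caudate_l", "rbsr_total"): -0.28,
    ("fa_t_dlpfc_caudate_l", "rbsr_stereotyped"): -0.24,
    ("fa_t_dlpfc_caudate_l", "rbsr_ritualistic"): -0.22,
    ("fa_t_dlpfc_caudate_l", "rbsr_sameness"): -0.27,
    ("fa_t_dlpfc_caudate_l", "rbsr_restricted_interests"): -0.27,
    ("fa_t_dlpfc_caudate_r", "rbsr_stereotyped"): -0.22,
    ("fa_t_dlpfc_caudate_r", "rbsr_restricted_interests"): -0.22,
    ("fa_t_sn_putamen_l", "rbsr_restricted_interests"): -0.20,
    ("fa_t_gpe_stn_r", "rbsr_sameness"): -0.21,
    ("fw_dlpfc_caudate_l", "rbsr_restricted_interests"): 0.23,
    ("fw_dlpfc_caudate_l", "scq"): 0.25,
    ("fw_dlpfc_caudate_r", "rbsr_restricted_interests"): 0.22,
    ("fw_dlpfc_caudate_r", "scq"): 0.21,
    ("fw_sn_putamen_l", "scq"): 0.26,
    ("fw_gpe_stn_l", "scq"): 0.22,
}

#: Male-minus-female shifts on tissue FA calibrated from the published sex-
#: effect F statistics (d ~ 2 sqrt(F/N) at N = 172).
_SEX_EFFECTS_FA_T = {
    "fa_t_sn_putamen_l": 0.0089,
    "fa_t_sn_putamen_r": 0.0130,
    "fa_t_gpe_stn_l": 0.0098,
    "fa_t_gpe_stn_r": 0.0098,
}

#: RBS-R subscale marginals; the published table prints only totals, so these
#: are plausible per-cell values consistent with it (restricted interests
#: carries the reported diagnosis-by-sex interaction, males > females in ASD).
_SUBSCALE_PARAMS = {
    "rbsr_stereotyped": (4.2, 3.6, 0.35, 1.2),
    "rbsr_self_injurious": (2.4, 3.0, 0.20, 0.9),
    "rbsr_compulsive": (3.0, 3.2, 0.25, 1.0),
    "rbsr_ritualistic": (3.6, 3.3, 0.30, 1.1),
    "rbsr_sameness": (5.1, 4.2, 0.40, 1.3),
    "rbsr_restricted_interests": {
        ("ASD", "M"): (4.5, 3.2), ("ASD", "F"): (2.6, 2.8),
        ("TD", "M"): (0.55, 1.3), ("TD", "F"): (0.20, 0.7),
    },
}

_BEHAVIOR_PARAMS = dict(
    iq=_IQ_PARAMS,
    rbsr_total=_RBSR_TOTAL_PARAMS,
    adir_c=_ADIR_PARAMS,
    scq=_SCQ_PARAMS,
    ados2=(12.0, 3.5, 0.0, 1.0),
    **_SUBSCALE_PARAMS,
)

_INTEGER_BEHAVIORS = ("rbsr_total", "rbsr_stereotyped", "rbsr_self_injurious",
                      "rbsr_compulsive", "rbsr_ritualistic", "rbsr_sameness",
                      "rbsr_restricted_interests", "adir_c", "scq", "ados2", "iq")


def demographic_cohort_spec(seed: int = 0) -> CohortSpec:
    """The full enrolled cohort: 91 ASD (42 M / 49 F) + 96 TD (52 M / 44 F)."""
    return CohortSpec(
        n_per_cell={("ASD", "M"): 42, ("ASD", "F"): 49,
                    ("TD", "M"): 52, ("TD", "F"): 44},
        behavior_params=_BEHAVIOR_PARAMS,
        age_params=_AGE_PARAMS,
        integer_behaviors=_INTEGER_BEHAVIORS,
        seed=seed,
    )


def diffusion_cohort_spec(seed: int = 0) -> CohortSpec:
    """The motion-passing diffusion cohort: 79 ASD / 93 TD.

    The published counts are 91 - 12 and 96 - 3; the excluded subjects' sexes
    are not printed, so cells are split proportionally to the enrolled cohort
    (ASD 36 M / 43 F, TD 50 M / 43 F). Tract metrics carry the published
    group means/SDs, the published sex effects on tissue FA, and the published
    brain-behavior Spearman links. A null per-subject mean head-motion metric
    is included for the motion group comparison.
    """
    metric_params = dict(FA_T_PARAMS)
    metric_params.update(FW_PARAMS)
    metric_params["motion_mean_rms"] = (0.52, 0.21, 0.50, 0.20)
    return CohortSpec(
        n_per_cell={("ASD", "M"): 36, ("ASD", "F"): 43,
                    ("TD", "M"): 50, ("TD", "F"): 43},
        metric_params=metric_params,
        behavior_params=_BEHAVIOR_PARAMS,
        behavior_link=dict(BEHAVIOR_LINKS),
        age_params=_AGE_PARAMS,
        sex_effect=dict(_SEX_EFFECTS_FA_T),
        integer_behaviors=_INTEGER_BEHAVIORS,
        seed=seed,
    )


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    return replace(spec, seed=seed)
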