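"""End-to-end orchestration: simulate -> QC -> fit -> volumes/profiles -> stats.

A run is driven by a :class:`RunConfig` (serializable to YAML) and writes a
directory tree::

    out_dir/
      config.yaml, manifest.json
      subjects/<id>/dwi.nii.gz, dwi.bval, dwi.bvec, mask.nii.gz,
                    labels.nii.gz, transforms.txt      (simulate)
      subjects/<id>/fw.nii.gz, fa_t.nii.gz, fa.nii.gz, md.nii.gz,
                    fit_qc.json                        (fit)
      qc_motion.csv                                    (qc)
      volumes.csv, cohort_metrics.csv                  (volumes/profiles)
      stats_tracts.csv, stats_volumes.csv, stats_motion.csv,
      stats_correlations.csv, slice_profiles/          (stats)
      report.csv                                       (make_report)

Stages are skipped when their outputs already exist and the config hash is
unchanged; all randomness derives from the config seed. The volumetric
analysis uses every quality-passing subject while the diffusion analysis uses
the motion-passing subset, mirroring designs where the two cohorts differ.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .cohort import read_metric_table, write_metric_table
from .core import Volume3D, ValidationError
from .freewater import fit_free_water, scalar_summary_in_mask
from .motion import apply_exclusion, motion_group_test, rotate_bvecs, summarize_motion
from .profiles import slice_group_test, slice_means, whole_tract_metric
from .stats import ancova_battery, correlation_battery
from .synthetic import (
    BiTensorGroundTruth,
    CohortSpec,
    eigenvalues_for_fa,
    make_gradient_scheme,
    make_tract_template,
    mirror_template,
    simulate_cohort,
    simulate_dwi,
    simulate_motion_trace,
)
from .volumetry import roi_volumes, volume_group_analysis

log = logging.getLogger("fwtract")

__all__ = ["RunConfig", "run_pipeline", "make_report"]


@dataclass
class RunConfig:
    """Configuration of a full synthetic pipeline run."""

    out_dir: str
    seed: int = 0
    n_per_cell: int = 5                 # subjects per diagnosis x sex cell
    grid_shape: tuple = (16, 16, 16)
    n_directions: int = 64
    snr: float = 40.0
    n_bad_volume_rate: float = 0.05     # fraction of DWIs with planted >2 mm motion
    flag_mm: float = 2.0
    max_fraction: float = 0.25
    min_ados: float = 7.0
    alpha: float = 0.05
    regularization_weight: float = 0.1
    tract_extent: int = 10
    # planted group parameters for the simulated tract (ASD mean, sd, TD mean, sd)
    fa_t_params: tuple = (0.441, 0.014, 0.450, 0.017)
    fw_params: tuple = (0.227, 0.028, 0.214, 0.025)
    behavior_rho: float = -0.28

    def __post_init__(self):
        if min(self.flag_mm, self.max_fraction, self.alpha) < 0 or self.min_ados < 0:
            raise ValidationError("thresholds must be non-negative")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("grid_shape", "fa_t_params", "fw_params"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _cohort_spec(cfg: RunConfig) -> CohortSpec:
    n = cfg.n_per_cell
    return CohortSpec(
        n_per_cell={("ASD", "M"): n, ("ASD", "F"): n,
                    ("TD", "M"): n, ("TD", "F"): n},
        metric_params={"true_fa_t": cfg.fa_t_params, "true_fw": cfg.fw_params},
        behavior_params={
            "ados2": (12.0, 3.5, 0.0, 1.0),
            "iq": (102.0, 20.4, 110.0, 15.4),
            "rbsr_total": (21.3, 16.8, 1.67, 5.07),
            "scq": (18.3, 7.36, 2.44, 3.20),
        },
        behavior_link={("true_fa_t", "rbsr_total"): cfg.behavior_rho},
        integer_behaviors=("ados2", "iq", "rbsr_total", "scq"),
        seed=cfg.seed,
    )


def _stage_done(out: Path, manifest: dict, stage: str, cfg_hash: str) -> bool:
    rec = manifest.get("stages", {}).get(stage)
    return bool(rec and rec.get("config_hash") == cfg_hash and
                all(Path(p).exists() for p in rec.get("outputs", [])))


def _record(manifest: dict, stage: str, cfg_hash: str, outputs, **extra):
    manifest.setdefault("stages", {})[stage] = dict(
        config_hash=cfg_hash, outputs=[str(p) for p in outputs], **extra
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, returning (and writing) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    cfg_hash = config.content_hash()
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest["config_hash"] = cfg_hash

    cohort = _simulate_stage(config, out, manifest, cfg_hash)
    cohort = _qc_stage(config, out, manifest, cfg_hash, cohort)
    _fit_stage(config, out, manifest, cfg_hash, cohort)
    cohort = _metrics_stage(config, out, manifest, cfg_hash, cohort)
    _stats_stage(config, out, manifest, cfg_hash, cohort)

    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# --------------------------------------------------------------------------
# stage: simulate

def _templates(cfg: RunConfig):
    left = make_tract_template(cfg.grid_shape, axis="Y", extent=cfg.tract_extent,
                               seed=cfg.seed + 7, name="sim_tract", hemisphere="L")
    return {"L": left, "R": mirror_template(left)}


def _simulate_stage(cfg, out, manifest, cfg_hash) -> pd.DataFrame:
    cohort_path = out / "cohort.csv"
    if _stage_done(out, manifest, "simulate", cfg_hash):
        log.info("simulate: outputs exist, skipping")
        return read_metric_table(cohort_path)
    spec = _cohort_spec(cfg)
    cohort = simulate_cohort(spec)
    gtab = make_gradient_scheme(cfg.n_directions, seed=cfg.seed)
    templates = _templates(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    shape = tuple(cfg.grid_shape)
    outputs = [cohort_path]
    for i, row in cohort.iterrows():
        sdir = out / "subjects" / row.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        f_map = np.full(shape, 0.25)
        fa_map = np.full(shape, 0.30)
        tract = templates["L"].mask | templates["R"].mask
        f_map[tract] = np.clip(row.true_fw, 0.0, 0.95)
        fa_map[tract] = np.clip(row.true_fa_t, 0.05, 0.95)
        evals = np.empty(shape + (3,))
        for fa in np.unique(fa_map):
            evals[fa_map == fa] = eigenvalues_for_fa(float(fa), 0.7e-3)
        ori = np.zeros(shape + (3,))
        ori[..., 1] = 1.0  # tract travels along Y
        ori[~tract] = rng.standard_normal((int((~tract).sum()), 3))
        truth = BiTensorGroundTruth(f_map, evals, ori, np.full(shape, 400.0))
        dwi = simulate_dwi(truth, gtab, snr=cfg.snr, seed=cfg.seed + 100 + i)
        fio.save_volume(dwi, sdir / "dwi.nii.gz")
        fio.write_gradient_table(gtab, sdir / "dwi.bval", sdir / "dwi.bvec")
        mask = Volume3D(np.ones(shape, np.uint8), dwi.affine)
        fio.save_volume(mask, sdir / "mask.nii.gz")
        # two spherical ROIs with per-subject size jitter, for volumetry
        labels = np.zeros(shape, np.int16)
        cx = np.array(shape) / 2.0
        ijk = np.indices(shape).reshape(3, -1).T
        r = 3.0 + 0.5 * rng.standard_normal()
        d2 = ((ijk - (cx - [4, 0, 0])) ** 2).sum(axis=1)
        labels.reshape(-1)[d2 < r**2] = 1
        d2 = ((ijk - (cx + [4, 0, 0])) ** 2).sum(axis=1)
        labels.reshape(-1)[d2 < (r + 0.2 * rng.standard_normal()) ** 2] = 2
        fio.save_volume(Volume3D(labels.astype(float), dwi.affine),
                        sdir / "labels.nii.gz")
        n_dwi = cfg.n_directions
        n_bad = int(rng.binomial(n_dwi, cfg.n_bad_volume_rate))
        trans = simulate_motion_trace(n_dwi, n_bad, magnitude_mm=3.0,
                                      seed=cfg.seed + 200 + i)
        full = np.concatenate([np.eye(4)[None], trans])  # identity for the b0
        fio.write_transforms(full, sdir / "transforms.txt")
        outputs += [sdir / "dwi.nii.gz"]
    write_metric_table(cohort, cohort_path)
    _record(manifest, "simulate", cfg_hash, outputs, n_subjects=len(cohort))
    return cohort


# --------------------------------------------------------------------------
# stage: qc

def _qc_stage(cfg, out, manifest, cfg_hash, cohort) -> pd.DataFrame:
    qc_path = out / "qc_motion.csv"
    if _stage_done(out, manifest, "qc", cfg_hash):
        qc = pd.read_csv(qc_path)
    else:
        rows = []
        for _, row in cohort.iterrows():
            sdir = out / "subjects" / row.subject_id
            _, gtab = fio.read_dwi(sdir / "dwi.nii.gz", sdir / "dwi.bval",
                                   sdir / "dwi.bvec")
            mask = fio.load_volume3d(sdir / "mask.nii.gz")
            trans = fio.read_transforms(sdir / "transforms.txt")
            summ = summarize_motion(trans, mask, gtab, flag_mm=cfg.flag_mm)
            decision = apply_exclusion(summ, cfg.flag_mm, cfg.max_fraction)
            rotated = rotate_bvecs(gtab, trans)
            fio.write_gradient_table(rotated, sdir / "dwi_rotated.bval",
                                     sdir / "dwi_rotated.bvec")
            rows.append(dict(subject_id=row.subject_id,
                             n_flagged=int(summ.flags.sum()),
                             fraction_flagged=summ.fraction_flagged,
                             motion_mean_rms=summ.subject_mean_rms,
                             decision=decision))
        qc = pd.DataFrame(rows)
        qc.to_csv(qc_path, index=False, float_format="%.17g")
        n_excl = int((qc.decision == "exclude").sum())
        assert len(qc) == n_excl + int((qc.decision == "retain").sum())
        _record(manifest, "qc", cfg_hash, [qc_path], n_input=len(qc),
                n_retained=len(qc) - n_excl, n_excluded=n_excl,
                excluded=[s for s in qc.loc[qc.decision == "exclude", "subject_id"]])
        for sid in qc.loc[qc.decision == "exclude", "subject_id"]:
            log.info("excluded %s: >%.0f%% volumes with >%g mm motion",
                     sid, 100 * cfg.max_fraction, cfg.flag_mm)
    cohort = cohort.merge(qc[["subject_id", "motion_mean_rms", "decision"]],
                          on="subject_id")
    return cohort


# --------------------------------------------------------------------------
# stage: fit

def _fit_stage(cfg, out, manifest, cfg_hash, cohort) -> None:
    if _stage_done(out, manifest, "fit", cfg_hash):
        return
    outputs = []
    for _, row in cohort.iterrows():
        if row.decision != "retain":
            continue
        sdir = out / "subjects" / row.subject_id
        dwi, _ = fio.read_dwi(sdir / "dwi.nii.gz", sdir / "dwi.bval", sdir / "dwi.bvec")
        gtab = fio.read_gradient_table(sdir / "dwi_rotated.bval",
                                       sdir / "dwi_rotated.bvec")
        mask = fio.load_volume3d(sdir / "mask.nii.gz")
        fit = fit_free_water(dwi, gtab, mask,
                             regularization_weight=cfg.regularization_weight)
        for name, vol in [("fw", fit.fw), ("fa_t", fit.fa_t),
                          ("fa", fit.fa), ("md", fit.md)]:
            fio.save_volume(vol, sdir / f"{name}.nii.gz")
            outputs.append(sdir / f"{name}.nii.gz")
        qc = {k: v for k, v in fit.convergence.items() if np.isscalar(v) or
              isinstance(v, (int, float))}
        qc["pure_water_fraction"] = float(fit.pure_water.mean())
        (sdir / "fit_qc.json").write_text(json.dumps(qc, indent=2))
    _record(manifest, "fit", cfg_hash, outputs)


# --------------------------------------------------------------------------
# stage: volumes + tract metrics

def _metrics_stage(cfg, out, manifest, cfg_hash, cohort) -> pd.DataFrame:
    vol_path = out / "volumes.csv"
    metrics_path = out / "cohort_metrics.csv"
    if _stage_done(out, manifest, "metrics", cfg_hash):
        return read_metric_table(metrics_path)
    templates = _templates(cfg)
    label_names = {1: "roi_left", 2: "roi_right"}
    vol_rows, metric_rows = [], []
    for _, row in cohort.iterrows():
        sdir = out / "subjects" / row.subject_id
        labels = fio.load_labels(sdir / "labels.nii.gz", label_names)
        mask = fio.load_volume3d(sdir / "mask.nii.gz")
        vols = roi_volumes(labels, mask, subject_id=row.subject_id)
        vol_rows.append(vols)
        rec = dict(subject_id=row.subject_id, tbv_mm3=vols.tbv_mm3.iloc[0])
        for _, v in vols.iterrows():
            rec[f"vol_pct_{v.roi}"] = v.pct_tbv
        if row.decision == "retain":
            for name in ("fa_t", "fw"):
                m = fio.load_volume3d(sdir / f"{name}.nii.gz")
                for hemi, tpl in templates.items():
                    rec[f"{name}_sim_tract_{hemi.lower()}"] = whole_tract_metric(m, tpl)
        metric_rows.append(rec)
    pd.concat(vol_rows).to_csv(vol_path, index=False, float_format="%.17g")
    metrics = cohort.merge(pd.DataFrame(metric_rows), on="subject_id")
    write_metric_table(metrics, metrics_path)
    _record(manifest, "metrics", cfg_hash, [vol_path, metrics_path])
    return metrics


# --------------------------------------------------------------------------
# stage: stats

def _stats_stage(cfg, out, manifest, cfg_hash, cohort) -> None:
    if _stage_done(out, manifest, "stats", cfg_hash):
        return
    outputs = []
    diff = cohort[cohort.decision == "retain"]
    fa_cols = [c for c in cohort.columns if c.startswith("fa_t_sim")]
    fw_cols = [c for c in cohort.columns if c.startswith("fw_sim")]
    vol_cols = [c for c in cohort.columns if c.startswith("vol_pct_")]
    # tract-level ANCOVA, FDR separately for the FA_T and FW families
    tract_tabs = []
    for family, cols in [("fa_t", fa_cols), ("fw", fw_cols)]:
        tab = ancova_battery(diff, cols)
        tab.insert(0, "family", family)
        tract_tabs.append(tab)
    tract_stats = pd.concat(tract_tabs, ignore_index=True)
    tract_stats.to_csv(out / "stats_tracts.csv", index=False, float_format="%.17g")
    outputs.append(out / "stats_tracts.csv")
    # volumetric ANCOVA on all quality-passing subjects
    vol_stats = volume_group_analysis(cohort, vol_cols, mode="percent")
    vol_stats.to_csv(out / "stats_volumes.csv", index=False, float_format="%.17g")
    outputs.append(out / "stats_volumes.csv")
    # residual-motion group check
    mot = motion_group_test(diff)
    mot.to_csv(out / "stats_motion.csv", index=False, float_format="%.17g")
    outputs.append(out / "stats_motion.csv")
    # slice-level follow-up, gated on whole-tract FDR-significant diagnosis effects
    sig = tract_stats[(tract_stats.effect == "diagnosis")
                      & (tract_stats.p_fdr < cfg.alpha)]
    templates = _templates(cfg)
    prof_dir = out / "slice_profiles"
    prof_dir.mkdir(exist_ok=True)
    for outcome in sig.outcome:
        name = "fa_t" if outcome.startswith("fa_t") else "fw"
        hemi = outcome.rsplit("_", 1)[1].upper()
        tpl = templates[hemi]
        profs = {"ASD": [], "TD": []}
        for _, row in diff.iterrows():
            m = fio.load_volume3d(out / "subjects" / row.subject_id / f"{name}.nii.gz")
            profs[row.diagnosis].append(slice_means(m, tpl))
        res = slice_group_test(pd.DataFrame(profs["ASD"]), pd.DataFrame(profs["TD"]),
                               alpha=cfg.alpha)
        res.table.to_csv(prof_dir / f"{outcome}_slices.csv", index=False,
                         float_format="%.17g")
        outputs.append(prof_dir / f"{outcome}_slices.csv")
    # brain-behavior correlations, per-family FDR
    corr = correlation_battery(
        diff,
        families={"fa_t": fa_cols, "fw": fw_cols, "volume": vol_cols},
        behavior_columns=["rbsr_total", "scq", "ados2"],
        asd_only_behaviors=("ados2",),
    )
    corr.to_csv(out / "stats_correlations.csv", index=False, float_format="%.17g")
    outputs.append(out / "stats_correlations.csv")
    _record(manifest, "stats", cfg_hash, outputs,
            n_diffusion=len(diff), n_volumetric=len(cohort))


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def make_report(out_dir) -> pd.DataFrame:
    """Summary table: per outcome, group mean +/- SD and per-effect raw/FDR p
    with significance markers (*, **, *** at p_FDR < 0.05/0.01/0.001)."""
    out = Path(out_dir)
    stats_path = out / "stats_tracts.csv"
    if not stats_path.exists():
        raise ValidationError("stats stage has not produced stats_tracts.csv")
    stats = pd.read_csv(stats_path)
    cohort = read_metric_table(out / "cohort_metrics.csv")
    diff = cohort[cohort.decision == "retain"]
    rows = []
    for outcome, tab in stats.groupby("outcome", sort=False):
        rec = dict(outcome=outcome)
        for dx in ("ASD", "TD"):
            vals = diff.loc[diff.diagnosis == dx, outcome]
            rec[f"{dx}_mean_sd"] = f"{vals.mean():.3f} ± {vals.std(ddof=1):.3f}"
        for _, r in tab.iterrows():
            rec[f"p_raw_{r.effect}"] = r.p_raw
            rec[f"p_fdr_{r.effect}"] = f"{r.p_fdr:.3g}{_stars(r.p_fdr)}"
        rows.append(rec)
    report = pd.DataFrame(rows)
    report.to_csv(out / "report.csv", index=False)
    return report
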