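"""Cohort records, inclusion filtering, and the tabular metric format.

A cohort table is a pandas DataFrame with one row per subject. Required
columns: ``subject_id, diagnosis, sex, age_months, scanner``; behavior and
imaging-metric columns are free-form. Missing behavior scores are explicit
nulls (NaN) and are dropped per-analysis, never globally, because the study
design analyzes behavior on smaller ns than imaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import ValidationError

__all__ = ["SubjectRecord", "cohort_filter", "write_metric_table", "read_metric_table"]

DIAGNOSES = ("ASD", "TD")
SEXES = ("M", "F")
SCANNERS = ("TrioTim", "Prisma")

#: RBS-R subscales scored by the generator and the statistics battery.
RBSR_SUBSCALES = (
    "rbsr_stereotyped",
    "rbsr_self_injurious",
    "rbsr_compulsive",
    "rbsr_ritualistic",
    "rbsr_sameness",
    "rbsr_restricted_interests",
)


@dataclass
class SubjectRecord:
    """Demographics, covariates and clinical scores for one participant.

    ADOS-2 and ADI-R section C are administered only to the ASD group, so
    they are optional and must be absent (None) for TD subjects.
    """

    id: str
    diagnosis: str
    sex: str
    age_months: float
    scanner: str
    iq: Optional[float] = None
    ados2: Optional[float] = None
    rbsr_total: Optional[float] = None
    rbsr_stereotyped: Optional[float] = None
    rbsr_self_injurious: Optional[float] = None
    rbsr_compulsive: Optional[float] = None
    rbsr_ritualistic: Optional[float] = None
    rbsr_sameness: Optional[float] = None
    rbsr_restricted_interests: Optional[float] = None
    adir_c: Optional[float] = None
    scq: Optional[float] = None

    def __post_init__(self):
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(f"diagnosis must be one of {DIAGNOSES}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}")
        if self.scanner not in SCANNERS:
            raise ValidationError(f"scanner must be one of {SCANNERS}")
        if self.diagnosis == "TD" and self.adir_c is not None:
            raise ValidationError("ADI-R section C is scored only in the ASD group")


def cohort_filter(records: Iterable[SubjectRecord], min_ados: float = 7):
    """Apply the ASD inclusion cutoff on the ADOS-2 calibrated score.

    ASD records with ``ados2 < min_ados`` are excluded; the assessment is not
    given to TD participants, so TD records are never excluded on ADOS.

    Returns
    -------
    (retained, excluded) : two lists forming an exhaustive, disjoint partition.
    """
    if min_ados < 0:
        raise ValidationError("min_ados must be >= 0")
    retained, excluded = [], []
    for rec in records:
        if rec.diagnosis == "ASD":
            if rec.ados2 is None:
                raise ValidationError(
                    f"ASD subject {rec.id} lacks a required ADOS-2 score"
                )
            (retained if rec.ados2 >= min_ados else excluded).append(rec)
        else:
            retained.append(rec)
    return retained, excluded


def records_to_table(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records]).rename(columns={"id": "subject_id"})
    return df


def write_metric_table(cohort: pd.DataFrame, path) -> None:
    """Write a cohort/metric table as CSV with a header row.

    Floats are written with repr-exact precision so that a round-trip read
    reproduces values bit-exactly.
    """
    if len(cohort) == 0:
        raise ValidationError("refusing to write an empty cohort table")
    if "subject_id" not in cohort.columns:
        raise ValidationError("cohort table needs a subject_id column")
    dup = cohort["subject_id"][cohort["subject_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate subject ids: {sorted(set(dup))}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False, float_format="%.17g")


def read_metric_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValidationError(f"{path} is not a cohort table (no subject_id column)")
    df["subject_id"] = df["subject_id"].astype(str)
    return df
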