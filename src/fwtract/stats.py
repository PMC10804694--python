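"""Group statistics: 2x2 ANCOVA, FDR families, simple effects, Spearman batteries.

The group model throughout is a linear model with intercept, diagnosis, sex,
their interaction, and covariates, under sum-to-zero factor coding. Because
every factor has two levels, each effect occupies a single design column and
its Type-III partial F equals the squared t of that coefficient in the full
model; this closed form lets one design matrix serve many outcome columns at
once, which the null-calibration simulations rely on. Tests cross-check the
F values against statsmodels' Type-III ANOVA.

Effect tables use df_den = N - p where p is the number of model columns
(6 for the standard model with age and scanner covariates: with the study's
172 diffusion-passing subjects this gives the familiar F(1, 166)).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import ValidationError

__all__ = [
    "ancova_2x2",
    "ancova_battery",
    "simple_effect",
    "bh_fdr",
    "spearman_corr",
    "correlation_battery",
]

_FACTOR_CODING = {
    # sum-to-zero: first listed level -> +1, second -> -1
    "diagnosis": ("ASD", "TD"),
    "sex": ("F", "M"),
    "scanner": ("Prisma", "TrioTim"),
}


def _code_factor(values: pd.Series, name: str) -> np.ndarray:
    levels = _FACTOR_CODING.get(name)
    if levels is None:
        levels = tuple(sorted(pd.unique(values.dropna())))
    if len(levels) != 2:
        raise ValidationError(f"factor {name} must have exactly 2 levels, got {levels}")
    coded = np.where(values == levels[0], 1.0, np.where(values == levels[1], -1.0, np.nan))
    if np.isnan(coded).any():
        bad = sorted(set(values[np.isnan(coded)]))
        raise ValidationError(f"factor {name} has levels outside {levels}: {bad}")
    return coded


def _build_design(
    data: pd.DataFrame,
    factors: Sequence[str],
    covariates: Sequence[str],
) -> tuple[np.ndarray, list[str]]:
    n = len(data)
    f1, f2 = factors
    levels1 = _FACTOR_CODING.get(f1, tuple(sorted(data[f1].unique())))
    levels2 = _FACTOR_CODING.get(f2, tuple(sorted(data[f2].unique())))
    for l1 in levels1:
        for l2 in levels2:
            cell_n = int(((data[f1] == l1) & (data[f2] == l2)).sum())
            if cell_n < 2:
                raise ValidationError(
                    f"cell ({f1}={l1}, {f2}={l2}) has {cell_n} observations (need >= 2)"
                )
    c1 = _code_factor(data[f1], f1)
    c2 = _code_factor(data[f2], f2)
    cols = [np.ones(n), c1, c2, c1 * c2]
    names = ["intercept", f1, f2, f"{f1}:{f2}"]
    for cov in covariates:
        vals = data[cov]
        if vals.dtype == object or str(vals.dtype) == "category":
            cols.append(_code_factor(vals, cov))
        else:
            cols.append(np.asarray(vals, dtype=float))
        names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(f"rank-deficient design; columns {names}")
    return X, names


def _glm_partial_f(X: np.ndarray, Y: np.ndarray, effect_idx: Sequence[int]):
    """Partial F per single-df effect for each outcome column of Y.

    Returns (F, p, df_den) with F, p of shape (n_effects, n_outcomes).
    """
    n, p = X.shape
    df_den = n - p
    if df_den <= 0:
        raise ValidationError(f"no residual df: n={n}, model columns={p}")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)  # (p, m)
    resid = Y - X @ beta
    sigma2 = np.einsum("nm,nm->m", resid, resid) / df_den  # (m,)
    idx = np.asarray(effect_idx)
    var_beta = np.outer(np.diag(xtx_inv)[idx], sigma2)  # (k, m)
    # a residual variance at rounding-error scale means a degenerate
    # (constant-fit) outcome: report F = 0 rather than 0/0 noise
    scale = np.einsum("nm,nm->m", Y, Y) / n
    degenerate = sigma2 <= scale * 1e-24
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(var_beta > 0, beta[idx] ** 2 / var_beta, 0.0)
    F[:, degenerate] = 0.0
    pvals = sps.f.sf(F, 1, df_den)
    return F, pvals, df_den


def ancova_2x2(
    data: pd.DataFrame,
    outcome: str | Sequence[str],
    covariates: Sequence[str] = ("age_months", "scanner"),
    factors: Sequence[str] = ("diagnosis", "sex"),
) -> pd.DataFrame:
    """2x2 ANCOVA of one or more outcomes on diagnosis x sex plus covariates.

    Rows with a missing outcome value are dropped per-outcome (listwise within
    each test), reproducing analysis-specific ns.

    Returns
    -------
    DataFrame with columns outcome, effect, F, df_num, df_den, p_raw.
    """
    outcomes = [outcome] if isinstance(outcome, str) else list(outcome)
    effect_names = [factors[0], factors[1], f"{factors[0]}:{factors[1]}"]
    # group outcomes by identical missingness pattern so complete-case sets
    # can still share a design matrix
    rows = []
    cols_needed = list(factors) + list(covariates)
    miss = {oc: tuple(np.flatnonzero(data[oc].isna())) for oc in outcomes}
    for pattern in sorted(set(miss.values())):
        ocs = [oc for oc in outcomes if miss[oc] == pattern]
        sub = data.drop(index=data.index[list(pattern)]) if pattern else data
        if sub[cols_needed].isna().any().any():
            raise ValidationError("missing factor/covariate values")
        X, names = _build_design(sub, factors, covariates)
        idx = [names.index(e) for e in effect_names]
        Y = sub[ocs].to_numpy(dtype=float)
        F, pvals, df_den = _glm_partial_f(X, Y, idx)
        for j, oc in enumerate(ocs):
            for i, eff in enumerate(effect_names):
                rows.append(
                    dict(outcome=oc, effect=eff, F=F[i, j], df_num=1,
                         df_den=df_den, p_raw=pvals[i, j])
                )
    out = pd.DataFrame(rows)
    # preserve caller's outcome order
    out["__o"] = out["outcome"].map({oc: k for k, oc in enumerate(outcomes)})
    out = out.sort_values(["__o"], kind="stable").drop(columns="__o").reset_index(drop=True)
    return out


def ancova_battery(
    data: pd.DataFrame,
    outcomes: Sequence[str],
    covariates: Sequence[str] = ("age_months", "scanner"),
    factors: Sequence[str] = ("diagnosis", "sex"),
) -> pd.DataFrame:
    """ANCOVA over a family of outcomes with BH-FDR applied across outcomes,
    separately per effect (the study's correction scheme for ROI and tract
    families)."""
    table = ancova_2x2(data, list(outcomes), covariates=covariates, factors=factors)
    table["p_fdr"] = np.nan
    for eff in table["effect"].unique():
        sel = table["effect"] == eff
        table.loc[sel, "p_fdr"] = bh_fdr(table.loc[sel, "p_raw"].to_numpy())
    return table


def simple_effect(
    data: pd.DataFrame,
    outcome: str,
    factor: str,
    within: tuple[str, str] | None = None,
    covariates: Sequence[str] = ("age_months",),
) -> tuple[float, float, int]:
    """Post-hoc one-way GLM of ``factor`` within one group level.

    E.g. the effect of sex on restricted-interests scores within the ASD
    group, covarying age. Returns (F, p, df_den).
    """
    sub = data if within is None else data[data[within[0]] == within[1]]
    sub = sub.dropna(subset=[outcome])
    if len(sub) == 0:
        raise ValidationError("empty subset for simple effect")
    c = _code_factor(sub[factor], factor)
    cols = [np.ones(len(sub)), c]
    for cov in covariates:
        vals = sub[cov]
        if vals.dtype == object:
            cols.append(_code_factor(vals, cov))
        else:
            cols.append(np.asarray(vals, dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("rank-deficient design in simple effect")
    F, p, df_den = _glm_partial_f(X, sub[[outcome]].to_numpy(dtype=float), [1])
    return float(F[0, 0]), float(p[0, 0]), df_den


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value family")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with listwise deletion of null pairs.

    Returns (rho, p) with p from the t approximation on n - 2 df; a constant
    input yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise ValidationError(f"need >= 4 complete pairs, got {len(x)}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def correlation_battery(
    cohort: pd.DataFrame,
    families: Mapping[str, Sequence[str]],
    behavior_columns: Sequence[str],
    asd_only_behaviors: Sequence[str] = ("adir_c",),
) -> pd.DataFrame:
    """All (metric, behavior) Spearman correlations with per-family BH-FDR.

    ``families`` maps a family name (e.g. "fa_t", "fw", "volume") to its
    metric columns; FDR is applied within each family across all its
    (metric, behavior) pairs. Behaviors in ``asd_only_behaviors`` (clinical
    instruments administered only to the ASD group) are correlated on ASD
    rows only.
    """
    rows = []
    for family, metrics in families.items():
        if len(metrics) == 0:
            raise ValidationError(f"family {family} covers zero tests")
        for metric in metrics:
            for beh in behavior_columns:
                sub = cohort if beh not in asd_only_behaviors else cohort[
                    cohort["diagnosis"] == "ASD"
                ]
                rho, p = spearman_corr(sub[metric], sub[beh])
                rows.append(
                    dict(family=family, metric=metric, behavior=beh,
                         n=int((~(sub[metric].isna() | sub[beh].isna())).sum()),
                         rho=rho, p_raw=p)
                )
    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    for family in families:
        sel = (table["family"] == family) & table["p_raw"].notna()
        if sel.any():
            table.loc[sel, "p_fdr"] = bh_fdr(table.loc[sel, "p_raw"].to_numpy())
    return table
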