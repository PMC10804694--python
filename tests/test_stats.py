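"""The statistical engine: Type-III 2x2 ANCOVA, BH-FDR, Spearman batteries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fwtract import (
    ValidationError,
    ancova_2x2,
    ancova_battery,
    bh_fdr,
    correlation_battery,
    simple_effect,
    spearman_corr,
)
from fwtract.synthetic import demographic_cohort_spec, diffusion_cohort_spec, simulate_cohort


def balanced_fixture():
    """16 rows, 4 per diagnosis x sex cell, with age and scanner covariates."""
    rows = []
    rng = np.random.default_rng(42)
    for dx in ("ASD", "TD"):
        for sex in ("M", "F"):
            for k in range(4):
                rows.append(dict(
                    diagnosis=dx, sex=sex,
                    age_months=float(rng.integers(80, 200)),
                    scanner="TrioTim" if k % 2 else "Prisma",
                    y=float(rng.standard_normal()),
                ))
    return pd.DataFrame(rows)


def _oracle_type3(df, outcome, covariates):
    """Normal-equations oracle: full-vs-reduced model comparison per effect."""
    d = np.where(df.diagnosis == "ASD", 1.0, -1.0)
    s = np.where(df.sex == "F", 1.0, -1.0)
    cols = {"intercept": np.ones(len(df)), "diagnosis": d, "sex": s,
            "diagnosis:sex": d * s}
    for cov in covariates:
        if cov == "scanner":
            cols["scanner"] = np.where(df.scanner == "Prisma", 1.0, -1.0)
        else:
            cols[cov] = df[cov].to_numpy(dtype=float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    y = df[outcome].to_numpy(dtype=float)

    def sse(Xm):
        beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        r = y - Xm @ beta
        return r @ r

    sse_full = sse(X)
    df_den = len(df) - X.shape[1]
    out = {}
    for eff in ("diagnosis", "sex", "diagnosis:sex"):
        keep = [i for i, n in enumerate(names) if n != eff]
        F = (sse(X[:, keep]) - sse_full) / (sse_full / df_den)
        out[eff] = (F, df_den)
    return out


class TestAncova:
    def test_balanced_fixture_matches_normal_equations_oracle(self):
        df = balanced_fixture()
        got = ancova_2x2(df, "y", covariates=("age_months", "scanner"))
        oracle = _oracle_type3(df, "y", ("age_months", "scanner"))
        for _, row in got.iterrows():
            F_exp, df_den = oracle[row.effect]
            assert row.F == pytest.approx(F_exp, abs=1e-10)
            assert row.df_den == df_den

    def test_matches_statsmodels_type3(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = balanced_fixture()
        model = smf.ols(
            "y ~ C(diagnosis, Sum) * C(sex, Sum) + age_months + C(scanner, Sum)",
            data=df,
        ).fit()
        table = sm.stats.anova_lm(model, typ=3)
        got = ancova_2x2(df, "y").set_index("effect")
        assert got.loc["diagnosis", "F"] == pytest.approx(
            table.loc["C(diagnosis, Sum)", "F"], rel=1e-8)
        assert got.loc["sex", "F"] == pytest.approx(
            table.loc["C(sex, Sum)", "F"], rel=1e-8)
        assert got.loc["diagnosis:sex", "F"] == pytest.approx(
            table.loc["C(diagnosis, Sum):C(sex, Sum)", "F"], rel=1e-8)

    def test_no_covariate_balanced_case_equals_classical_anova(self):
        """On balanced data with no covariates the Type-III F equals the
        classical cell-mean two-way ANOVA decomposition."""
        df = balanced_fixture()
        got = ancova_2x2(df, "y", covariates=()).set_index("effect")
        # classical sums of squares from cell means (balanced: n per cell)
        cells = df.groupby(["diagnosis", "sex"]).y.mean()
        grand = df.y.mean()
        n = 4
        ss_dx = 2 * n * sum((cells.groupby("diagnosis").mean() - grand) ** 2)
        ss_sex = 2 * n * sum((cells.groupby("sex").mean() - grand) ** 2)
        ss_int = n * sum(
            (cells[dx, sx] - cells.groupby("diagnosis").mean()[dx]
             - cells.groupby("sex").mean()[sx] + grand) ** 2
            for dx in ("ASD", "TD") for sx in ("M", "F"))
        sse = sum((df.y - df.groupby(["diagnosis", "sex"]).y.transform("mean")) ** 2)
        ms_err = sse / (16 - 4)
        assert got.loc["diagnosis", "F"] == pytest.approx(ss_dx / ms_err, rel=1e-10)
        assert got.loc["sex", "F"] == pytest.approx(ss_sex / ms_err, rel=1e-10)
        assert got.loc["diagnosis:sex", "F"] == pytest.approx(ss_int / ms_err,
                                                              rel=1e-10)

    def test_residual_df_166_with_study_cohort(self):
        """172 diffusion-passing subjects and the 6-column model give the
        familiar F(1, 166) denominator."""
        df = simulate_cohort(diffusion_cohort_spec(seed=0))
        assert len(df) == 172
        tab = ancova_2x2(df, "fa_t_dlpfc_caudate_l")
        assert (tab.df_den == 166).all()
        assert (tab.df_num == 1).all()

    def test_residual_df_183_for_demographic_anova(self):
        """187 enrolled subjects, 2x2 ANOVA without covariates -> df 183."""
        df = simulate_cohort(demographic_cohort_spec(seed=0))
        assert len(df) == 187
        tab = ancova_2x2(df, "iq", covariates=())
        assert (tab.df_den == 183).all()

    def test_constant_outcome_gives_zero_f(self):
        df = balanced_fixture()
        df["y"] = 5.0
        tab = ancova_2x2(df, "y")
        assert (tab.F == 0.0).all()

    def test_empty_cell_rejected_with_cell_named(self):
        df = balanced_fixture()
        df = df[~((df.diagnosis == "ASD") & (df.sex == "F"))]
        with pytest.raises(ValidationError, match="ASD.*F|F.*ASD"):
            ancova_2x2(df, "y")

    def test_rank_deficient_design_rejected(self):
        df = balanced_fixture()
        df["dup"] = df.age_months
        with pytest.raises(ValidationError, match="rank"):
            ancova_2x2(df, "y", covariates=("age_months", "dup"))

    def test_missing_outcomes_dropped_per_analysis(self):
        df = simulate_cohort(diffusion_cohort_spec(seed=1))
        df.loc[df.index[:12], "fa_t_dlpfc_caudate_l"] = np.nan
        tab = ancova_2x2(df, ["fa_t_dlpfc_caudate_l", "fw_dlpfc_caudate_l"])
        by = tab.set_index(["outcome", "effect"])
        assert by.loc[("fa_t_dlpfc_caudate_l", "diagnosis"), "df_den"] == 172 - 12 - 6
        assert by.loc[("fw_dlpfc_caudate_l", "diagnosis"), "df_den"] == 166


class TestSimpleEffect:
    def test_two_group_toy_matches_t_squared(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(dict(
            diagnosis=["ASD"] * 20, sex=["M"] * 10 + ["F"] * 10,
            y=np.r_[rng.normal(1, 1, 10), rng.normal(0, 1, 10)],
        ))
        F, p, df_den = simple_effect(df, "y", "sex", covariates=())
        t, pt = sps.ttest_ind(df.y[df.sex == "M"], df.y[df.sex == "F"])
        assert F == pytest.approx(t**2, rel=1e-10)
        assert p == pytest.approx(pt, rel=1e-10)
        assert df_den == 18

    def test_constant_outcome_zero_f(self):
        df = pd.DataFrame(dict(diagnosis=["ASD"] * 8, sex=["M", "F"] * 4,
                               age_months=np.arange(8.0) + 100, y=1.0))
        F, p, _ = simple_effect(df, "y", "sex")
        assert F == 0.0

    def test_within_group_subsetting(self):
        df = simulate_cohort(demographic_cohort_spec(seed=3))
        F, p, df_den = simple_effect(df, "rbsr_restricted_interests", "sex",
                                     within=("diagnosis", "ASD"))
        n_asd = (df.diagnosis == "ASD").sum()
        assert df_den == n_asd - 3  # intercept + sex + age


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.005, 0.03, 0.04]),
                                   [0.015, 0.04, 0.04])

    def test_all_equal_and_singleton(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)
        np.testing.assert_allclose(bh_fdr([0.31]), [0.31])

    def test_matches_brute_force_step_up(self):
        """q_(i) = min_{j >= i} m p_(j) / j, capped at 1, by explicit loops."""
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = int(rng.integers(1, 12))
            p = rng.uniform(size=m)
            got = bh_fdr(p)
            order = np.argsort(p, kind="stable")
            ps = p[order]
            q_sorted = [
                min(min(m * ps[j] / (j + 1) for j in range(i, m)), 1.0)
                for i in range(m)
            ]
            expect = np.empty(m)
            expect[order] = q_sorted
            np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_adjusted_at_least_raw_and_monotone_in_rank(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=20)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_corr([1, 2, 3, 4, 5], [10, 20, 25, 40, 100])
        assert rho == pytest.approx(1.0)

    def test_three_point_hand_formula(self):
        """x=[1,2,3], y=[3,1,2]: rho = 1 - 6*6/(3*8) = -0.5 (needs n >= 4 in
        the public API, so check on the doubled sequence preserving ranks is
        not equivalent; use scipy-free rank formula directly)."""
        ranks_x = np.array([1, 2, 3])
        ranks_y = np.array([3, 1, 2])
        d2 = ((ranks_x - ranks_y) ** 2).sum()
        rho_hand = 1 - 6 * d2 / (3 * (9 - 1))
        assert rho_hand == -0.5
        rho_scipy = sps.spearmanr([1, 2, 3], [3, 1, 2]).statistic
        assert rho_scipy == pytest.approx(-0.5)

    def test_nulls_dropped_pairwise(self):
        x = [1, 2, np.nan, 4, 5, 6]
        y = [2, 4, 5, np.nan, 10, 12]
        rho, p = spearman_corr(x, y)
        assert rho == pytest.approx(1.0)

    def test_constant_input_returns_nan(self):
        rho, p = spearman_corr([1.0] * 6, [1, 2, 3, 4, 5, 6])
        assert np.isnan(rho) and np.isnan(p)

    def test_p_close_to_exhaustive_permutation_oracle_n7(self):
        """The t-approximation p agrees with the exact permutation null
        (all 7! = 5040 permutations) to within a few percent."""
        x = np.arange(7.0)
        y = np.array([2.0, 0.0, 3.0, 1.0, 6.0, 4.0, 5.0])
        rho_obs, p_t = spearman_corr(x, y)
        count = 0
        for perm in itertools.permutations(range(7)):
            rho = sps.spearmanr(x, np.array(perm, float)).statistic
            if abs(rho) >= abs(rho_obs) - 1e-12:
                count += 1
        p_exact = count / 5040
        assert p_t == pytest.approx(p_exact, abs=0.05)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        rho0, _ = spearman_corr(x, y)
        rho1, _ = spearman_corr(np.exp(2 * x), y**3 + 5 * y)
        assert rho1 == pytest.approx(rho0, abs=1e-12)


class TestCorrelationBattery:
    def test_adir_restricted_to_asd_rows(self):
        df = simulate_cohort(diffusion_cohort_spec(seed=2))
        tab = correlation_battery(
            df, {"fa_t": ["fa_t_dlpfc_caudate_l"]},
            behavior_columns=["adir_c", "rbsr_total"],
        )
        n_adir = tab.loc[tab.behavior == "adir_c", "n"].iloc[0]
        n_rbsr = tab.loc[tab.behavior == "rbsr_total", "n"].iloc[0]
        assert n_adir == (df.diagnosis == "ASD").sum()
        assert n_rbsr == len(df)

    def test_fdr_within_declared_families(self):
        df = simulate_cohort(diffusion_cohort_spec(seed=4))
        tab = correlation_battery(
            df,
            {"fa_t": ["fa_t_dlpfc_caudate_l", "fa_t_gpe_stn_r"],
             "fw": ["fw_dlpfc_caudate_l"]},
            behavior_columns=["rbsr_total", "scq"],
        )
        for fam, sub in tab.groupby("family"):
            np.testing.assert_allclose(sub.p_fdr.to_numpy(),
                                       bh_fdr(sub.p_raw.to_numpy()))

    def test_empty_family_rejected(self):
        df = simulate_cohort(diffusion_cohort_spec(seed=4))
        with pytest.raises(ValidationError):
            correlation_battery(df, {"fa_t": []}, behavior_columns=["scq"])


def test_ancova_battery_fdr_per_effect():
    df = simulate_cohort(diffusion_cohort_spec(seed=9))
    cols = ["fa_t_dlpfc_caudate_l", "fa_t_dlpfc_caudate_r", "fa_t_gpe_stn_l"]
    tab = ancova_battery(df, cols)
    for eff, sub in tab.groupby("effect"):
        np.testing.assert_allclose(sub.p_fdr.to_numpy(), bh_fdr(sub.p_raw.to_numpy()))
    assert (tab.p_fdr >= tab.p_raw - 1e-15).all()
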