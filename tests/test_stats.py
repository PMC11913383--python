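"""Mixed-model condition comparisons: fits, Wald tests, R², contrasts.

Includes a dual-route check of the contrast machinery against the
reference R implementation (lme4/lmerTest + emmeans) on a small fixture.
"""

import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from circumkin import (
    default_design,
    default_presets,
    fit_lmm,
    pairwise_contrasts,
    r2_nakagawa,
    simulate_experiment,
    wald_type3,
)
from circumkin.synthetic import ExperimentDesign, METRICS


def make_design(n_plants, seed, intercept_sd=None, residual_sd=None, null=False):
    d = default_design(n_plants_per_condition=n_plants, seed=seed)
    kw = dict(vars(d))
    if intercept_sd is not None:
        kw["random_intercept_sd"] = {m: intercept_sd for m in METRICS}
    if residual_sd is not None:
        kw["residual_sd"] = {m: residual_sd for m in METRICS}
    if null:
        kw["fixed_effects"] = {m: {} for m in METRICS}
    return ExperimentDesign(**kw)


@pytest.fixture(scope="module")
def records():
    design = default_design(n_plants_per_condition=8, seed=3)
    rec, _ = simulate_experiment(design, default_presets())
    return rec


@pytest.fixture(scope="module")
def fit(records):
    return fit_lmm(records, "avg_velocity_mm_min")


class TestFitLMM:
    def test_shape_and_components(self, fit):
        assert fit.n_obs == 64 and fit.n_plants == 32
        assert fit.levels[0] == "US" and len(fit.beta) == 4
        assert fit.sigma2_plant >= 0 and fit.sigma2_resid > 0

    def test_zero_plant_variance_reduces_to_ols(self):
        """With no plant variance the GLS fit equals ordinary least squares."""
        design = make_design(20, 5, intercept_sd=0.0)
        rec, _ = simulate_experiment(design, default_presets())
        f = fit_lmm(rec, "avg_velocity_mm_min")
        import statsmodels.api as sm

        ols = sm.OLS(rec["avg_velocity_mm_min"].to_numpy(), f.X).fit()
        assert np.allclose(f.beta.to_numpy(), ols.params, atol=1e-4)
        assert f.sigma2_plant < 0.05 * f.sigma2_resid

    def test_variance_components_recovered(self):
        """Programmed intercept sd 2, residual sd 1 recovered within 20%
        relative at 100 plants per condition."""
        design = make_design(100, 11, intercept_sd=2.0, residual_sd=1.0)
        rec, _ = simulate_experiment(design, default_presets())
        f = fit_lmm(rec, "movement_time_min")
        assert np.sqrt(f.sigma2_plant) == pytest.approx(2.0, rel=0.2)
        assert np.sqrt(f.sigma2_resid) == pytest.approx(1.0, rel=0.2)

    def test_deposit_shaped_table(self):
        """A per-observation table of 115 observations across 52 plants fits
        with those counts (the study's model dimensions)."""
        rng = np.random.default_rng(0)
        plants = [f"P{i:02d}" for i in range(52)]
        conds = np.repeat(["US", "LS", "IS", "DS"], 13)
        rows = []
        k = 0
        while k < 115:
            i = k % 52
            rows.append(
                {
                    "plant_id": plants[i],
                    "condition": conds[i],
                    "avg_velocity_mm_min": rng.normal(2.0, 1.0),
                }
            )
            k += 1
        f = fit_lmm(pd.DataFrame(rows), "avg_velocity_mm_min")
        assert f.n_obs == 115 and f.n_plants == 52

    @pytest.mark.parametrize("missing", ["condition", "plant_id"])
    def test_missing_columns_rejected(self, records, missing):
        with pytest.raises(ValueError):
            fit_lmm(records.drop(columns=[missing]), "avg_velocity_mm_min")

    def test_single_condition_rejected(self, records):
        with pytest.raises(ValueError):
            fit_lmm(records[records["condition"] == "US"], "avg_velocity_mm_min")


class TestWaldType3:
    def test_table_structure(self, fit):
        w = wald_type3(fit)
        assert list(w["term"]) == ["(Intercept)", "Condition"]
        assert (w["chisq"] >= 0).all()
        assert w.loc[1, "df"] == 3

    def test_null_calibration(self):
        """Under no condition effect the type-III p-value is uniform:
        rejection rate at α=0.05 within the binomial CI over 300 replicates."""
        n_rep, alpha = 300, 0.05
        rejections = 0
        for rep in range(n_rep):
            design = make_design(6, 10_000 + rep, null=True)
            rec, _ = simulate_experiment(design, default_presets())
            f = fit_lmm(rec, "avg_velocity_mm_min")
            rejections += wald_type3(f).loc[1, "p"] < alpha
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rejections / n_rep - alpha) < 3 * se + 0.01

    def test_shift_invariance(self, records, fit):
        """Adding a constant to all responses changes no condition χ²,
        no contrast, and no R²."""
        shifted = records.copy()
        shifted["avg_velocity_mm_min"] += 100.0
        f2 = fit_lmm(shifted, "avg_velocity_mm_min")
        assert wald_type3(f2).loc[1, "chisq"] == pytest.approx(
            wald_type3(fit).loc[1, "chisq"], rel=1e-4
        )
        c1 = pairwise_contrasts(fit)["estimate"].to_numpy()
        c2 = pairwise_contrasts(f2)["estimate"].to_numpy()
        assert np.allclose(c1, c2, atol=1e-5)
        assert r2_nakagawa(f2) == pytest.approx(r2_nakagawa(fit), abs=1e-4)


class TestR2Nakagawa:
    def test_zero_fixed_effects_marginal_zero(self):
        design = make_design(30, 21, null=True)
        rec, _ = simulate_experiment(design, default_presets())
        r2m, r2c = r2_nakagawa(fit_lmm(rec, "avg_velocity_mm_min"))
        assert r2m < 0.05

    def test_no_plant_variance_marginal_equals_conditional(self):
        """With zero programmed plant variance the R² gap is exactly the
        (boundary-biased, small) estimated intercept variance share."""
        design = make_design(100, 22, intercept_sd=0.0)
        rec, _ = simulate_experiment(design, default_presets())
        f = fit_lmm(rec, "avg_velocity_mm_min")
        r2m, r2c = r2_nakagawa(f)
        fitted_var = np.var(f.X @ f.beta.to_numpy(), ddof=1)
        denom = fitted_var + f.sigma2_plant + f.sigma2_resid
        assert r2c - r2m == pytest.approx(f.sigma2_plant / denom, abs=1e-10)
        assert r2c - r2m < 0.05

    def test_programmed_variance_partition(self):
        """varF:varPlant:varResid = 1:1:2 gives (R²m, R²c) = (0.25, 0.50)
        within 0.03 at 200 plants per condition."""
        # condition shifts (−√2·c, −c/√2... ) chosen so var(fixed fitted) = 1
        shifts = {"US": 0.0, "LS": 1.0, "IS": 2.0, "DS": 3.0}
        base = np.array(list(shifts.values()))
        scale = 1.0 / np.std(np.repeat(base, 10), ddof=1)  # population-balanced
        fe = {m: {c: v * scale for c, v in shifts.items()} for m in METRICS}
        design = ExperimentDesign(
            n_plants_per_condition=200,
            baselines={m: 0.0 for m in METRICS},
            fixed_effects=fe,
            random_intercept_sd={m: 1.0 for m in METRICS},
            residual_sd={m: np.sqrt(2.0) for m in METRICS},
            observations_per_plant=2,
            seed=31,
        )
        rec, _ = simulate_experiment(design, default_presets())
        r2m, r2c = r2_nakagawa(fit_lmm(rec, "cycle_length_mm"))
        assert r2m == pytest.approx(0.25, abs=0.03)
        assert r2c == pytest.approx(0.50, abs=0.03)

    def test_all_zero_variance_rejected(self, fit):
        broken = fit
        import copy

        broken = copy.copy(fit)
        broken.beta = fit.beta * 0.0
        broken.sigma2_plant = 0.0
        broken.sigma2_resid = 0.0
        with pytest.raises(ValueError):
            r2_nakagawa(broken)


class TestPairwiseContrasts:
    def test_six_contrasts_consistent_with_means(self, fit):
        ct = pairwise_contrasts(fit)
        assert len(ct) == 6
        em = fit.emmeans()
        for _, row in ct.iterrows():
            a, b = row["contrast"].split(" - ")
            assert row["estimate"] == pytest.approx(em[a] - em[b], abs=1e-8)
            assert row["t"] == pytest.approx(row["estimate"] / row["SE"], rel=1e-8)

    def test_tukey_adjustment_not_smaller_than_unadjusted(self, fit):
        tk = pairwise_contrasts(fit, adjust="tukey")["p_adj"].to_numpy()
        un = pairwise_contrasts(fit, adjust="none")["p_adj"].to_numpy()
        assert np.all(tk >= un - 1e-12)

    def test_satterthwaite_df_positive_and_bounded(self, fit):
        ct = pairwise_contrasts(fit)
        assert (ct["df"] > 0).all()
        assert (ct["df"] <= fit.n_obs - len(fit.beta) + 1e-6).all()

    def test_balanced_zero_plant_variance_matches_pooled_ols_se(self):
        """With no plant variance the contrast SE is the two-sample pooled
        OLS standard error."""
        design = make_design(40, 41, intercept_sd=0.0)
        rec, _ = simulate_experiment(design, default_presets())
        rec = rec.drop_duplicates("plant_id")
        f = fit_lmm(rec, "peak_velocity_time_pct")
        ct = pairwise_contrasts(f, adjust="none")
        import statsmodels.api as sm

        ols = sm.OLS(rec["peak_velocity_time_pct"].to_numpy(), f.X).fit()
        pooled_se = np.sqrt(2.0 * ols.scale / 40.0)
        assert ct["SE"].to_numpy() == pytest.approx(pooled_se, rel=0.05)

    def test_programmed_contrast_recovered(self):
        """Programmed US−LS average-velocity effect of +1.95 mm/min is
        recovered within 2 SE at 50 plants per condition."""
        design = make_design(50, 51)
        rec, truth = simulate_experiment(design, default_presets())
        f = fit_lmm(rec, "avg_velocity_mm_min")
        ct = pairwise_contrasts(f)
        row = ct[ct["contrast"] == "US - LS"].iloc[0]
        assert abs(row["estimate"] - 1.95) < 2 * row["SE"]

    def test_unknown_method_names_rejected(self, fit):
        with pytest.raises(ValueError):
            pairwise_contrasts(fit, df_method="bogus")
        with pytest.raises(ValueError):
            pairwise_contrasts(fit, adjust="bonferroni")

    def test_kenward_roger_close_to_satterthwaite_when_balanced(self, fit):
        sat = pairwise_contrasts(fit, df_method="satterthwaite")
        kr = pairwise_contrasts(fit, df_method="kenward_roger")
        assert kr["SE"].to_numpy() == pytest.approx(sat["SE"].to_numpy(), rel=0.05)
        assert kr["df"].to_numpy() == pytest.approx(sat["df"].to_numpy(), rel=0.15)


class TestAgainstRReference:
    def test_matches_lmerTest_emmeans(self, tmp_path, records):
        """Estimates, SEs, Satterthwaite dfs and Tukey p-values agree with
        lme4/lmerTest + emmeans on an unbalanced fixture."""
        rng = np.random.default_rng(7)
        rec = records.drop(
            index=rng.choice(records.index, 15, replace=False)
        ).reset_index(drop=True)
        csv = tmp_path / "records.csv"
        rec.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages({{library(lmerTest); library(emmeans); library(jsonlite)}})
                d <- read.csv("{csv}")
                d$condition <- relevel(factor(d$condition), ref="US")
                m <- lmer(avg_velocity_mm_min ~ condition + (1|plant_id), d, REML=TRUE)
                em <- emmeans(m, pairwise ~ condition, lmer.df="satterthwaite")
                ct <- as.data.frame(em$contrasts)
                vc <- as.data.frame(VarCorr(m))
                cat(toJSON(list(contrast=ct$contrast, estimate=ct$estimate,
                                SE=ct$SE, df=ct$df, p=ct$p.value,
                                s2_plant=vc$vcov[1], s2_resid=vc$vcov[2]),
                           digits=10))
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)

        f = fit_lmm(rec, "avg_velocity_mm_min")
        assert f.sigma2_plant == pytest.approx(ref["s2_plant"][0], rel=1e-3)
        assert f.sigma2_resid == pytest.approx(ref["s2_resid"][0], rel=1e-3)
        ct = pairwise_contrasts(f).set_index("contrast")
        for i, name in enumerate(ref["contrast"]):
            row = ct.loc[name]
            assert row["estimate"] == pytest.approx(ref["estimate"][i], abs=1e-5)
            assert row["SE"] == pytest.approx(ref["SE"][i], rel=1e-3)
            assert row["df"] == pytest.approx(ref["df"][i], rel=0.02)
            assert row["p_adj"] == pytest.approx(ref["p"][i], abs=0.005)
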