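"""Mixed-effects growth model: fitting, screening, tests, percent growth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from airwaymorph import growth
from airwaymorph.growth import (
    BONFERRONI_ALPHA,
    OUTLIER_CUTOFF,
    GrowthModelFit,
    age_group_summary,
    exclude_outliers,
    fit_growth_model,
    growth_analysis,
    lrt_age_effect,
    percent_growth,
    significance_flag,
    validate_growth_data,
    wald_sex_contrast,
)
from airwaymorph.phantom import simulate_growth_data

BETAS = (8.0, 0.12, 0.9, 0.08, 0.16, 0.03)


def hand_fit(beta, vcov=None, sigma_subject2=0.01, sigma_resid2=0.01):
    beta = np.asarray(beta, dtype=float)
    if vcov is None:
        vcov = np.eye(6) * 1e-4
    return GrowthModelFit(
        beta=beta, vcov=vcov, sigma_subject2=sigma_subject2, sigma_resid2=sigma_resid2,
        loglik=0.0, n_obs=100, n_subjects=50, converged=True,
    )


class TestFit:
    def test_noiseless_data_recovers_beta_exactly(self):
        df = simulate_growth_data(30, 1, betas=BETAS, sigma_subject=0.0, sigma_resid=0.0, seed=3)
        fit = fit_growth_model(df)
        np.testing.assert_allclose(fit.beta, BETAS, atol=1e-8)

    def test_zero_subject_variance_is_boundary(self):
        df = simulate_growth_data(60, 2, betas=BETAS, sigma_subject=0.0, sigma_resid=0.1, seed=5)
        fit = fit_growth_model(df)
        assert fit.sigma_subject2 == pytest.approx(0.0, abs=5e-3)

    def test_single_sex_rejected(self):
        df = simulate_growth_data(20, 1, seed=1)
        with pytest.raises(ValueError, match="sex"):
            fit_growth_model(df[df.sex == 1])

    def test_variable_column_filtering(self):
        df = simulate_growth_data(20, 1, seed=2, variable="Nasopharynx")
        fit = fit_growth_model(df, "Nasopharynx")
        assert fit.n_obs == len(df)
        with pytest.raises(ValueError, match="no rows"):
            fit_growth_model(df, "Oropharynx")

    def test_invariant_validation(self):
        df = simulate_growth_data(20, 1, seed=2)
        bad = df.copy()
        bad.loc[bad.index[0], "pediatric_age"] = 2.0
        bad.loc[bad.index[0], "adult"] = 1
        with pytest.raises(ValueError, match="adult"):
            validate_growth_data(bad)
        bad2 = df.copy()
        bad2.loc[bad2.index[0], "value"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            validate_growth_data(bad2)


class TestOutliers:
    def test_cutoff_is_two_sided_1pct_normal_quantile(self):
        assert OUTLIER_CUTOFF == round(float(stats.norm.ppf(0.995)), 3)
        assert OUTLIER_CUTOFF == 2.576

    def test_clean_data_unchanged(self):
        df = simulate_growth_data(12, 1, betas=BETAS, sigma_subject=0.1,
                                  sigma_resid=0.05, seed=8)
        filtered, excluded, _ = exclude_outliers(df)
        assert len(excluded) == 0
        pd.testing.assert_frame_equal(filtered, df)

    def test_planted_outlier_excluded(self):
        df = simulate_growth_data(50, 2, betas=BETAS, sigma_subject=0.15,
                                  sigma_resid=0.1, seed=9)
        target = df.index[17]
        df.loc[target, "value"] *= np.exp(10 * 0.1)  # +10 residual SD on log scale
        filtered, excluded, _ = exclude_outliers(df)
        assert list(excluded) == [target]
        assert target not in filtered.index


class TestLRT:
    def test_statistic_non_negative(self):
        df = simulate_growth_data(40, 2, betas=BETAS, sigma_subject=0.1,
                                  sigma_resid=0.1, seed=10)
        res = lrt_age_effect(df)
        assert res.statistic >= 0.0
        assert res.df == 2.0

    def test_strong_age_effect_detected(self):
        strong = (8.0, 0.1, 1.2, 0.0, 0.25, 0.0)
        hits = 0
        for i in range(5):
            df = simulate_growth_data(60, 2, betas=strong, sigma_subject=0.1,
                                      sigma_resid=0.1, seed=100 + i)
            if lrt_age_effect(df).p_value < 0.001:
                hits += 1
        assert hits == 5


class TestWald:
    def test_adult_contrast_reduces_to_sex_main_effect(self):
        fit = hand_fit([8.0, 0.25, 0.9, 0.0, 0.1, 0.02])
        res = wald_sex_contrast(fit, "adult")
        assert res.estimate == pytest.approx(0.25)

    def test_age5_contrast_algebra(self):
        fit = hand_fit([8.0, 0.2, 0.9, 0.1, 0.1, 0.04])
        res = wald_sex_contrast(fit, "age5")
        assert res.estimate == pytest.approx(0.2 + 5 * 0.04)

    def test_standard_error_matches_brute_force(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(6, 6))
        vcov = a @ a.T / 100.0
        fit = hand_fit([8.0, 0.2, 0.9, 0.1, 0.1, 0.04], vcov=vcov)
        c = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 5.0])
        res = wald_sex_contrast(fit, "age5")
        brute = 0.0
        for i in range(6):
            for j in range(6):
                brute += c[i] * vcov[i, j] * c[j]
        assert res.std_error == pytest.approx(np.sqrt(brute))
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(res.estimate / res.std_error)))

    def test_unknown_timepoint_rejected(self):
        with pytest.raises(ValueError, match="timepoint"):
            wald_sex_contrast(hand_fit(np.zeros(6)), "age3")


class TestPercentGrowth:
    def test_flat_model_is_100_percent(self):
        fit = hand_fit([8.0, 0.2, 0.0, 0.0, 0.0, 0.0])
        assert percent_growth(fit, sex=1) == pytest.approx(100.0)
        assert percent_growth(fit, sex=0) == pytest.approx(100.0)

    def test_hand_computed_value(self):
        # eta_ped(5) = 1 + 0.25, eta_adult = 1 + 0.5 -> 100 * exp(-0.25)
        fit = hand_fit([1.0, 0.0, 0.5, 0.0, 0.05, 0.0])
        assert percent_growth(fit, sex=0) == pytest.approx(100.0 * np.exp(-0.25))
        assert percent_growth(fit, sex=0) == pytest.approx(77.8800783, abs=1e-4)

    def test_monotone_in_age_slope(self):
        vals = [percent_growth(hand_fit([1.0, 0.0, 0.5, 0.0, b4, 0.0]), sex=1)
                for b4 in (0.01, 0.05, 0.1)]
        assert vals[0] < vals[1] < vals[2]

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(shift=st.floats(min_value=-3.0, max_value=3.0))
    def test_invariant_under_rescaling(self, shift):
        # multiplying the raw variable by c shifts b0 by log(c) and nothing else
        base = np.array([8.0, 0.1, 0.9, 0.05, 0.15, 0.02])
        shifted = base.copy()
        shifted[0] += shift
        for sex in (0, 1):
            assert percent_growth(hand_fit(base), sex) == pytest.approx(
                percent_growth(hand_fit(shifted), sex)
            )


class TestAgeGroups:
    def toy(self, rows):
        return pd.DataFrame(
            [
                {"subject_id": f"S{i}", "scan_id": f"S{i}-0", "sex": s, "adult": a,
                 "pediatric_age": g, "variable": "y", "value": v}
                for i, (s, a, g, v) in enumerate(rows)
            ]
        )

    def test_constant_values(self):
        out = age_group_summary(self.toy([(1, 0, 0.5, 3.0), (1, 0, 0.6, 3.0)]))
        row = out[(out.sex == 1) & (out.age_group == "<1")].iloc[0]
        assert row["mean"] == 3.0
        assert row["sd"] == 0.0

    def test_group_edges(self):
        out = age_group_summary(self.toy([(0, 0, 0.99, 1.0), (0, 0, 1.0, 2.0)]))
        assert set(out.age_group.astype(str)) == {"<1", "1"}

    def test_mean_and_sd(self):
        out = age_group_summary(self.toy([(1, 1, 0.0, 4.0), (1, 1, 0.0, 6.0)]))
        row = out[out.age_group == "adult"].iloc[0]
        assert row["mean"] == pytest.approx(5.0)
        assert row["sd"] == pytest.approx(np.sqrt(2.0), abs=1e-3)

    def test_unassignable_age(self):
        with pytest.raises(ValueError, match="unassignable"):
            age_group_summary(self.toy([(1, 0, 5.5, 1.0)]))


class TestIndependentOracle:
    def test_fit_matches_lme4(self, tmp_path):
        """ML fit agrees with an independent lme4 fit of the same model."""
        import json
        import subprocess

        df = simulate_growth_data(50, 2, betas=BETAS, sigma_subject=0.15,
                                  sigma_resid=0.10, seed=77)
        csv = tmp_path / "growth.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
            suppressMessages(library(lme4))
            suppressMessages(library(jsonlite))
            d <- read.csv("{csv}")
            d$logy <- log(d$value)
            m <- lmer(logy ~ sex + adult + sex:adult + pediatric_age +
                      sex:pediatric_age + (1|subject_id), data=d, REML=FALSE)
            vc <- as.data.frame(VarCorr(m))
            cat(toJSON(list(beta=as.numeric(fixef(m)),
                            loglik=as.numeric(logLik(m)),
                            s2_subject=vc$vcov[1], s2_resid=vc$vcov[2]),
                       digits=12))
            """
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, check=True)
        ref = json.loads(out.stdout)
        fit = fit_growth_model(df)
        # lme4 orders terms: intercept, sex, adult, ped_age, sex:adult, sex:ped_age
        lme4_beta = np.asarray(ref["beta"])[[0, 1, 2, 4, 3, 5]]
        np.testing.assert_allclose(fit.beta, lme4_beta, atol=1e-5)
        assert fit.loglik == pytest.approx(ref["loglik"][0], abs=1e-4)
        assert fit.sigma_subject2 == pytest.approx(ref["s2_subject"][0], rel=1e-4)
        assert fit.sigma_resid2 == pytest.approx(ref["s2_resid"][0], rel=1e-4)


class TestReporting:
    def test_significance_tiers(self):
        assert significance_flag(0.2) == ""
        assert significance_flag(0.04) == "*"
        assert significance_flag(0.005) == "**"
        assert significance_flag(0.0005) == "***"
        assert significance_flag(0.0001) == "****"
        assert BONFERRONI_ALPHA == 0.0004

    def test_growth_analysis_table(self):
        frames = [
            simulate_growth_data(40, 2, betas=BETAS, sigma_subject=0.12,
                                 sigma_resid=0.08, seed=20, variable=v)
            for v in ("Nasopharynx", "PharynxLength")
        ]
        table = growth_analysis(pd.concat(frames, ignore_index=True))
        assert list(table.variable) == ["Nasopharynx", "PharynxLength"]
        for col in ("lrt_p", "wald_age0_p", "wald_age5_p", "wald_adult_p"):
            assert table[col].between(0, 1).all()
        assert (table.percent_growth_m > 0).all()
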