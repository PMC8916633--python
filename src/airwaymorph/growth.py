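"""Mixed-effects growth modelling of airway measurements.

Each variable is fitted on the log scale with the linear mixed model

    log y = b0 + b1*Sex + b2*Adult + b3*Sex*Adult
            + b4*PediatricAge + b5*Sex*PediatricAge + alpha_i + eps

where Sex is 1 for males, Adult is 1 for adult subjects (whose
PediatricAge is 0), and alpha_i is a per-subject random intercept that
absorbs repeat scans.  Fitting is by maximum likelihood (not REML) so that
likelihood-ratio tests between nested fixed-effect structures are valid.
Age effects are tested by an LRT dropping both pediatric-age terms; sex
differences by Wald contrasts at birth, age 5 and adulthood; percent
growth at age 5 compares modeled pediatric and adult means on the raw
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "OUTLIER_CUTOFF",
    "BONFERRONI_ALPHA",
    "GrowthModelFit",
    "TestResult",
    "validate_growth_data",
    "fit_growth_model",
    "exclude_outliers",
    "lrt_age_effect",
    "wald_sex_contrast",
    "percent_growth",
    "age_group_summary",
    "significance_flag",
    "growth_analysis",
]

#: Standardized-residual exclusion constant: the 0.995 standard-normal
#: quantile rounded to three decimals (two-sided 1% tail).
OUTLIER_CUTOFF = 2.576

#: Family-wise significance level after Bonferroni correction across the
#: variable panel.
BONFERRONI_ALPHA = 0.0004

_FIXED_EFFECTS = ("intercept", "sex", "adult", "sex_adult", "ped_age", "sex_ped_age")


@dataclass
class GrowthModelFit:
    """ML fit of the growth model for one variable, on log scale."""

    beta: np.ndarray
    vcov: np.ndarray
    sigma_subject2: float
    sigma_resid2: float
    loglik: float
    n_obs: int
    n_subjects: int
    converged: bool
    scale: str = "log"

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).reshape(6)
        self.vcov = np.asarray(self.vcov, dtype=float).reshape(6, 6)
        if not np.allclose(self.vcov, self.vcov.T, atol=1e-8):
            raise ValueError("vcov must be symmetric")
        if self.sigma_subject2 < -1e-12 or self.sigma_resid2 < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    estimate: float
    std_error: float
    label: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")


def validate_growth_data(data: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format growth table invariants."""
    required = {"subject_id", "sex", "adult", "pediatric_age", "value"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    if ((data["adult"] == 1) & (data["pediatric_age"] != 0)).any():
        raise ValueError("adult rows must have pediatric_age = 0")
    ped = data[data["adult"] == 0]
    if ((ped["pediatric_age"] < 0) | (ped["pediatric_age"] >= 6)).any():
        raise ValueError("pediatric ages must lie in [0, 6)")
    if (data["value"] <= 0).any():
        raise ValueError("values must be positive (log-transformable)")
    return data


def _select(data: pd.DataFrame, variable: str | None) -> pd.DataFrame:
    if variable is not None and "variable" in data.columns:
        data = data[data["variable"] == variable]
        if data.empty:
            raise ValueError(f"no rows for variable {variable!r}")
    return data


def _design(data: pd.DataFrame) -> np.ndarray:
    sex = data["sex"].to_numpy(dtype=float)
    adult = data["adult"].to_numpy(dtype=float)
    age = data["pediatric_age"].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(data)), sex, adult, sex * adult, age, sex * age])


def _fit_mixedlm(endog, exog, groups):
    model = sm.MixedLM(endog, exog, groups=groups)
    # boundary warnings (variance component near zero) are expected in
    # null simulations and on degenerate designs; the fit is still valid
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method="lbfgs")
        except Exception:
            res = model.fit(reml=False)
    return model, res


def fit_growth_model(data: pd.DataFrame, variable: str | None = None) -> GrowthModelFit:
    """Maximum-likelihood random-intercept fit on log-transformed values."""
    data = validate_growth_data(_select(data, variable))
    if data[data["sex"] == 1]["subject_id"].nunique() < 2 or data[data["sex"] == 0]["subject_id"].nunique() < 2:
        raise ValueError("need at least two subjects of each sex")
    if data["adult"].nunique() < 2:
        raise ValueError("need both adult and pediatric rows")

    y = np.log(data["value"].to_numpy(dtype=float))
    X = _design(data)
    model, res = _fit_mixedlm(y, X, data["subject_id"].to_numpy())
    k = model.k_fe
    return GrowthModelFit(
        beta=np.asarray(res.fe_params),
        vcov=np.asarray(res.cov_params())[:k, :k],
        sigma_subject2=float(np.asarray(res.cov_re)[0, 0]),
        sigma_resid2=float(res.scale),
        loglik=float(res.llf),
        n_obs=len(y),
        n_subjects=int(data["subject_id"].nunique()),
        converged=bool(res.converged),
    )


def exclude_outliers(
    data: pd.DataFrame,
    variable: str | None = None,
    cutoff: float = OUTLIER_CUTOFF,
) -> tuple[pd.DataFrame, pd.Index, GrowthModelFit]:
    """Single-pass residual screening and refit.

    Rows whose standardized conditional residual (observed minus fixed
    effects minus the predicted subject intercept, divided by the residual
    SD) exceeds ``cutoff`` in magnitude are removed and the model is
    refitted once on the remainder.
    """
    data = validate_growth_data(_select(data, variable))
    y = np.log(data["value"].to_numpy(dtype=float))
    X = _design(data)
    groups = data["subject_id"].to_numpy()
    model, res = _fit_mixedlm(y, X, groups)

    re = res.random_effects
    alpha = np.array([float(np.asarray(re[g]).ravel()[0]) for g in groups])
    cond_resid = y - X @ res.fe_params - alpha
    z = cond_resid / np.sqrt(res.scale)
    keep = np.abs(z) <= cutoff
    if not keep.any():
        raise ValueError("all rows excluded; pathological initial fit")
    excluded = data.index[~keep]
    filtered = data.loc[keep]
    refit = fit_growth_model(filtered)
    return filtered, excluded, refit


def lrt_age_effect(data: pd.DataFrame, variable: str | None = None) -> TestResult:
    """Likelihood-ratio test of the overall age effect in the first 5 years.

    The reduced model drops both pediatric-age terms (b4 = b5 = 0); the
    statistic is referred to chi-square with 2 degrees of freedom.
    """
    data = validate_growth_data(_select(data, variable))
    y = np.log(data["value"].to_numpy(dtype=float))
    X = _design(data)
    groups = data["subject_id"].to_numpy()
    _, full = _fit_mixedlm(y, X, groups)
    _, reduced = _fit_mixedlm(y, X[:, :4], groups)
    stat = max(2.0 * (full.llf - reduced.llf), 0.0)
    p = float(stats.chi2.sf(stat, df=2))
    return TestResult(statistic=float(stat), df=2.0, p_value=p,
                      estimate=float(stat), std_error=float("nan"), label="age_LRT")


_CONTRASTS = {
    "age0": np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0]),
    "age5": np.array([0.0, 1.0, 0.0, 0.0, 0.0, 5.0]),
    "adult": np.array([0.0, 1.0, 0.0, 1.0, 0.0, 0.0]),
}

_CONTRAST_LABELS = {"age0": "sex_age0", "age5": "sex_age5", "adult": "sex_adult"}


def wald_sex_contrast(fit: GrowthModelFit, timepoint: str) -> TestResult:
    """Wald test of the male-female difference at one evaluation age.

    ``timepoint`` is ``"age0"`` (contrast b1), ``"age5"`` (b1 + 5 b5) or
    ``"adult"`` (b1 + b3); the statistic is referred to the standard
    normal.
    """
    if timepoint not in _CONTRASTS:
        raise ValueError(f"timepoint must be one of {sorted(_CONTRASTS)}")
    c = _CONTRASTS[timepoint]
    est = float(c @ fit.beta)
    var = float(c @ fit.vcov @ c)
    if var <= 0 or not np.isfinite(var):
        raise ValueError("singular covariance; Wald contrast undefined")
    se = float(np.sqrt(var))
    z = est / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult(statistic=z, df=1.0, p_value=p, estimate=est, std_error=se,
                      label=_CONTRAST_LABELS[timepoint])


def percent_growth(fit: GrowthModelFit, sex: int, age: float = 5.0) -> float:
    """Modeled pediatric mean at ``age`` as a percentage of the adult mean.

    Both means are fixed-effect point estimates back-transformed from the
    log scale; the ratio is invariant to multiplicative rescaling of the
    raw variable.
    """
    b = fit.beta
    eta_ped = b[0] + b[1] * sex + b[4] * age + b[5] * sex * age
    eta_adult = b[0] + b[1] * sex + b[2] + b[3] * sex
    return float(100.0 * np.exp(eta_ped - eta_adult))


_AGE_GROUPS = ("<1", "1", "2", "3", "4", "adult")


def _age_group(adult: int, age: float) -> str:
    if adult:
        return "adult"
    if age < 0 or age >= 5:
        raise ValueError(f"unassignable age {age}")
    g = int(np.floor(age))
    return "<1" if g == 0 else str(g)


def age_group_summary(data: pd.DataFrame) -> pd.DataFrame:
    """Per-sex, per-age-group mean (SD) table.

    Pediatric groups are whole-year bins <1, 1, 2, 3, 4; adults form their
    own group.
    """
    data = validate_growth_data(data.copy())
    data["age_group"] = [
        _age_group(a, p) for a, p in zip(data["adult"], data["pediatric_age"])
    ]
    keys = ["variable", "sex", "age_group"] if "variable" in data.columns else ["sex", "age_group"]
    out = (
        data.groupby(keys, observed=True)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    out["age_group"] = pd.Categorical(out["age_group"], categories=_AGE_GROUPS, ordered=True)
    return out.sort_values(keys).reset_index(drop=True)


def significance_flag(p: float, bonferroni: float = BONFERRONI_ALPHA) -> str:
    """Asterisk tiers: * <.05, ** <.01, *** <.001, **** below Bonferroni."""
    if p < bonferroni:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def growth_analysis(
    data: pd.DataFrame,
    variables: list[str] | None = None,
    cutoff: float = OUTLIER_CUTOFF,
    bonferroni: float = BONFERRONI_ALPHA,
) -> pd.DataFrame:
    """Per-variable growth panel: outlier screen, LRT, Wald tests, percent growth."""
    validate_growth_data(data)
    if variables is None:
        variables = sorted(data["variable"].unique()) if "variable" in data.columns else [None]
    rows = []
    for var in variables:
        filtered, excluded, fit = exclude_outliers(data, var, cutoff=cutoff)
        lrt = lrt_age_effect(filtered)
        row = {
            "variable": var,
            "n_excluded": len(excluded),
            "lrt_p": lrt.p_value,
            "lrt_flag": significance_flag(lrt.p_value, bonferroni),
        }
        for tp in ("age0", "age5", "adult"):
            w = wald_sex_contrast(fit, tp)
            row[f"wald_{tp}_p"] = w.p_value
            row[f"wald_{tp}_flag"] = significance_flag(w.p_value, bonferroni)
        row["percent_growth_m"] = percent_growth(fit, sex=1)
        row["percent_growth_f"] = percent_growth(fit, sex=0)
        rows.append(row)
    return pd.DataFrame(rows)
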