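"""Classical statistics over a cohort of DS scores.

Operates on a tidy cohort table (``subject_id, sex, age`` + 19 vertebral DS
columns, C7..S1): sex-stratified descriptives with t-based confidence
intervals, Mann-Whitney sex comparisons, Spearman/Pearson age correlations,
an ANCOVA screen for sex-by-metric interactions (justifying sex-stratified
models), multiple linear regression with SEE and collinearity diagnostics,
and cross-validated LASSO selection.

The standard error of the estimate is always ``sqrt(SSR / (n - k - 1))``
with ``k`` the number of retained predictors; for the full linear model
``k = 19``, for LASSO the count of nonzero coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .errors import ValidationError
from .phantoms import VERTEBRAE

__all__ = [
    "validate_cohort",
    "load_cohort",
    "descriptive_stats",
    "sex_difference_test",
    "age_correlations",
    "ancova_interaction_screen",
    "AncovaScreen",
    "flag_outliers",
    "mlr_fit",
    "RegressionReport",
    "lasso_fit",
    "LassoReport",
]


def validate_cohort(df: pd.DataFrame, min_age: float = 21.0) -> pd.DataFrame:
    """Check the cohort schema and invariants; returns the frame unchanged."""
    missing = [c for c in ("subject_id", "sex", "age", *VERTEBRAE) if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    if not df["sex"].isin(["M", "F"]).all():
        raise ValidationError("sex must be 'M' or 'F'")
    if (df["age"] < min_age).any():
        warnings.warn(f"ages below the design minimum of {min_age} y are present")
    if (df[list(VERTEBRAE)] <= 0).any().any():
        raise ValidationError("DS values must be strictly positive")
    return df


def load_cohort(path, min_age: float = 21.0) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path), min_age=min_age)


def descriptive_stats(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-sex mean, SD, median, min, max and 95% t-CI for every DS variable.

    CI = mean +/- t_{0.975, n-1} * SD / sqrt(n); omitted (NaN, with a
    warning) for single-subject groups.
    """
    rows = []
    for sex, g in cohort.groupby("sex"):
        n = len(g)
        if n < 2:
            warnings.warn(f"sex group {sex!r} has {n} subject(s); CI omitted")
        for v in VERTEBRAE:
            x = g[v].to_numpy(dtype=float)
            mean, sd = x.mean(), x.std(ddof=1) if n > 1 else np.nan
            if n > 1:
                half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
                ci = (mean - half, mean + half)
            else:
                ci = (np.nan, np.nan)
            rows.append({
                "sex": sex, "variable": v, "n": n, "mean": mean, "sd": sd,
                "median": float(np.median(x)), "min": x.min(), "max": x.max(),
                "ci_lo": ci[0], "ci_hi": ci[1],
            })
    return pd.DataFrame(rows).set_index(["sex", "variable"])


def sex_difference_test(cohort: pd.DataFrame, variable: str,
                        method: str = "mannwhitney") -> float:
    """Two-sided p-value for a male/female difference in one DS variable.

    Mann-Whitney U by default (DS distributions are right-skewed); exact
    null distribution when both groups have n < 20, tie-corrected normal
    approximation otherwise. ``method='welch'`` switches to Welch's t.
    """
    x = cohort.loc[cohort["sex"] == "M", variable].to_numpy(dtype=float)
    y = cohort.loc[cohort["sex"] == "F", variable].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both sexes must be present")
    if method == "welch":
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    how = "exact" if (len(x) < 20 and len(y) < 20 and
                      len(np.unique(np.r_[x, y])) == len(x) + len(y)) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=how).pvalue)


def age_correlations(cohort: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Per-sex (r, p) between age and each DS variable; ties mid-ranked."""
    if method not in ("spearman", "pearson"):
        raise ValidationError("method must be 'spearman' or 'pearson'")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for sex, g in cohort.groupby("sex"):
        if len(g) < 4:
            raise ValidationError(f"sex group {sex!r} too small for correlations")
        age = g["age"].to_numpy(dtype=float)
        for v in VERTEBRAE:
            x = g[v].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(age) == 0:
                rows.append({"sex": sex, "variable": v, "r": np.nan,
                             "p": np.nan, "constant": True})
                continue
            r, p = corr(age, x)
            rows.append({"sex": sex, "variable": v, "r": float(r),
                         "p": float(p), "constant": False})
    return pd.DataFrame(rows).set_index(["sex", "variable"])


@dataclass(frozen=True)
class AncovaScreen:
    """Joint Wald screen of sex main + sex-by-metric interaction terms."""

    statistic: float
    df_num: int
    df_den: int
    p_joint: float
    p_min_term: float
    term_pvalues: pd.Series

    def stratify(self, alpha: float = 0.05) -> bool:
        """Whether sex-stratified models are warranted at level ``alpha``."""
        return self.p_joint < alpha


def ancova_interaction_screen(cohort: pd.DataFrame) -> AncovaScreen:
    """OLS of age on sex, the 19 metrics and all sex-by-metric interactions.

    The joint Wald F-test covers the 20 sex-related coefficients (sex main
    effect + 19 interactions). Raises on a singular design, naming the
    aliased columns.
    """
    validate_cohort(cohort)
    metrics = cohort[list(VERTEBRAE)].to_numpy(dtype=float)
    sex_ind = (cohort["sex"] == "M").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(cohort)), sex_ind, metrics,
                         sex_ind[:, None] * metrics])
    names = (["const", "sex[M]"] + list(VERTEBRAE)
             + [f"sex[M]:{v}" for v in VERTEBRAE])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept):
                aliased.append(names[j])
            else:
                kept.append(j)
        raise ValidationError(f"singular ANCOVA design; aliased columns: {aliased}")
    fit = sm.OLS(cohort["age"].to_numpy(dtype=float), X).fit()
    R = np.zeros((1 + len(VERTEBRAE), X.shape[1]))
    R[0, 1] = 1.0
    for i in range(len(VERTEBRAE)):
        R[1 + i, 2 + len(VERTEBRAE) + i] = 1.0
    wald = fit.f_test(R)
    pvals = pd.Series(fit.pvalues, index=names)
    sex_terms = pvals[["sex[M]"] + [f"sex[M]:{v}" for v in VERTEBRAE]]
    return AncovaScreen(
        statistic=float(wald.fvalue), df_num=int(wald.df_num),
        df_den=int(wald.df_denom), p_joint=float(wald.pvalue),
        p_min_term=float(sex_terms.min()), term_pvalues=sex_terms,
    )


def flag_outliers(cohort: pd.DataFrame, n_sd: float = 3.0) -> pd.DataFrame:
    """Boolean frame flagging DS values beyond ``n_sd`` SDs within each sex.

    Flags only; removal is a caller decision (``mlr_fit(screen_outliers=...)``).
    """
    flags = pd.DataFrame(False, index=cohort.index, columns=list(VERTEBRAE))
    for _, g in cohort.groupby("sex"):
        z = (g[list(VERTEBRAE)] - g[list(VERTEBRAE)].mean()) / g[list(VERTEBRAE)].std(ddof=1)
        flags.loc[g.index] = z.abs() > n_sd
    return flags


@dataclass
class RegressionReport:
    """OLS fit statistics, coefficients and collinearity diagnostics."""

    sex: str
    n: int
    k: int
    r: float
    r2: float
    adj_r2: float
    see_years: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    coefficients: pd.DataFrame  # coef, se, t, p per predictor (+ const)
    vif: pd.Series
    tolerance: pd.Series
    condition_indices: np.ndarray
    residuals: np.ndarray = field(repr=False)

    def summary(self) -> str:
        lines = [
            f"Age ~ 19 DS predictors ({self.sex}, n = {self.n})",
            "=" * 48,
            f"R / R2 / adj. R2   {self.r:.3f} / {self.r2:.3f} / {self.adj_r2:.3f}",
            f"SEE                {self.see_years:.2f} years",
            f"F({self.df1}, {self.df2})          {self.f_stat:.2f}  (p = {self.p_value:.4g})",
            f"max VIF            {self.vif.max():.2f} ({self.vif.idxmax()})",
            f"min tolerance      {self.tolerance.min():.3f} ({self.tolerance.idxmin()})",
            f"max cond. index    {self.condition_indices.max():.1f}",
        ]
        return "\n".join(lines)


def _condition_indices(X: np.ndarray) -> np.ndarray:
    """Condition indices of a design (intercept included, unit column lengths)."""
    Z = X / np.linalg.norm(X, axis=0)
    lam = np.linalg.eigvalsh(Z.T @ Z)
    lam = np.clip(lam, 1e-300, None)
    return np.sqrt(lam.max() / lam)[::-1]


def mlr_fit(cohort: pd.DataFrame, sex: str, screen_outliers: bool = False,
            collinearity: bool = True) -> RegressionReport:
    """OLS of age on the 19 DS values for one sex.

    Reports R, R2, adjusted R2, the SEE (``sqrt(SSR / (n - k - 1))``,
    k = 19), the overall F-test, per-predictor VIF (= 1 / (1 - R2_j) from
    auxiliary regressions), tolerance and SPSS-style condition indices of the
    unit-length-scaled design including the intercept. ``screen_outliers``
    drops subjects with any DS value beyond 3 within-sex SDs before fitting;
    ``collinearity=False`` skips the VIF/condition-index diagnostics (useful
    in simulation loops).
    """
    validate_cohort(cohort)
    sub = cohort[cohort["sex"] == sex]
    if screen_outliers:
        sub = sub[~flag_outliers(cohort).loc[sub.index].any(axis=1)]
    k = len(VERTEBRAE)
    n = len(sub)
    if n <= k + 1:
        raise ValidationError(f"need n > k + 1 = {k + 1} subjects, got {n}")
    X = sub[list(VERTEBRAE)].to_numpy(dtype=float)
    y = sub["age"].to_numpy(dtype=float)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValidationError("perfectly collinear predictors: design is singular")
    fit = sm.OLS(y, Xc).fit()
    see = float(np.sqrt(fit.ssr / (n - k - 1)))
    if collinearity:
        vif = {}
        for j, v in enumerate(VERTEBRAE):
            others = np.delete(X, j, axis=1)
            r2_aux = sm.OLS(X[:, j], sm.add_constant(others)).fit().rsquared
            vif[v] = np.inf if r2_aux >= 1.0 else 1.0 / (1.0 - r2_aux)
        vif = pd.Series(vif)
        cond = _condition_indices(Xc)
    else:
        vif = pd.Series(np.nan, index=list(VERTEBRAE))
        cond = np.array([np.nan])
    coef = pd.DataFrame({
        "coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues,
    })
    coef.index = ["const", *VERTEBRAE]
    return RegressionReport(
        sex=sex, n=n, k=k, r=float(np.sqrt(fit.rsquared)), r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj), see_years=see, f_stat=float(fit.fvalue),
        df1=k, df2=n - k - 1, p_value=float(fit.f_pvalue), coefficients=coef,
        vif=vif, tolerance=1.0 / vif, condition_indices=cond,
        residuals=np.asarray(fit.resid),
    )


@dataclass(frozen=True)
class LassoReport:
    """Cross-validated LASSO selection for one sex."""

    sex: str
    alpha: float
    nonzero: pd.Series  # original-scale coefficients of retained predictors
    k_nonzero: int
    test_r2: float
    test_see: float
    full_see: float
    cv_mae: float


def lasso_fit(cohort: pd.DataFrame, sex: str,
              alphas: np.ndarray | None = None, cv_folds: int = 10,
              seed: int = 42, test_fraction: float = 0.2) -> LassoReport:
    """LASSO of age on the 19 DS values with CV-selected penalty.

    The penalty is picked from a log-spaced grid (default 50 points in
    ``[1e-3, 10]``) minimizing cross-validated MAE inside the training split;
    predictors are standardized within training folds only. Reported
    coefficients are mapped back to the original DS scale. ``test_see`` uses
    ``k`` = number of nonzero coefficients; ``full_see`` refits the selected
    penalty on the full sex subsample.
    """
    from .ml import SplitSpec, make_split  # shared split logic

    if alphas is None:
        alphas = np.logspace(-3, 1, 50)
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size == 0 or np.any(alphas <= 0):
        raise ValidationError("alpha grid must be non-empty and positive")
    if cv_folds < 2:
        raise ValidationError("need at least 2 CV folds")
    validate_cohort(cohort)
    sub = cohort[cohort["sex"] == sex]
    train, test = make_split(sub, SplitSpec(test_fraction=test_fraction,
                                            cv_folds=cv_folds, seed=seed))
    pipe = Pipeline([("scale", StandardScaler()),
                     ("lasso", Lasso(max_iter=50_000))])
    search = GridSearchCV(
        pipe, {"lasso__alpha": alphas},
        scoring="neg_mean_absolute_error",
        cv=KFold(cv_folds, shuffle=True, random_state=seed),
    )
    cols = list(VERTEBRAE)
    search.fit(train[cols], train["age"])
    best = search.best_estimator_
    alpha = float(search.best_params_["lasso__alpha"])
    scale = best.named_steps["scale"].scale_
    coefs = pd.Series(best.named_steps["lasso"].coef_ / scale, index=cols)
    nonzero = coefs[best.named_steps["lasso"].coef_ != 0]
    k = int(len(nonzero))
    pred = best.predict(test[cols])
    resid = test["age"].to_numpy() - pred
    sst = np.sum((test["age"] - test["age"].mean()) ** 2)
    test_r2 = float(1.0 - np.sum(resid**2) / sst) if sst > 0 else np.nan
    test_see = float(np.sqrt(np.sum(resid**2) / max(1, len(test) - k - 1)))
    full = Pipeline([("scale", StandardScaler()),
                     ("lasso", Lasso(alpha=alpha, max_iter=50_000))])
    full.fit(sub[cols], sub["age"])
    full_resid = sub["age"].to_numpy() - full.predict(sub[cols])
    full_see = float(np.sqrt(np.sum(full_resid**2) / max(1, len(sub) - k - 1)))
    return LassoReport(sex=sex, alpha=alpha, nonzero=nonzero, k_nonzero=k,
                       test_r2=test_r2, test_see=test_see, full_see=full_see,
                       cv_mae=float(-search.best_score_))
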