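"""Machine-learning age regression over the 19 DS predictors.

Protocol: one shuffled 80/20 hold-out split per sex, 10-fold cross-validated
grid search inside the training portion with fold-wise standardization (the
scaler lives inside the pipeline, so its parameters are estimated on each
fold's training part only), evaluation on the untouched hold-out with
percentile-bootstrap confidence intervals, plus diagnostics: permutation
importance, Bland-Altman agreement and learning curves.

Learners: RBF and linear SVR, random forest, k-nearest neighbours, and a
discretized Gaussian naive-Bayes pseudo-regressor (age binned at empirical
quantiles, Gaussian NB on the bin labels, prediction projected back to the
continuous scale as the posterior-weighted bin midpoint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import mean_absolute_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import ValidationError
from .phantoms import VERTEBRAE

__all__ = [
    "MODEL_NAMES",
    "SplitSpec",
    "ModelGrid",
    "EvalReport",
    "GNBRegressor",
    "make_split",
    "tune_model",
    "evaluate",
    "permutation_importance",
    "bland_altman",
    "BlandAltman",
    "learning_curve",
]

MODEL_NAMES = ("svr_rbf", "svr_lin", "rf", "knn", "gnb_reg")


@dataclass(frozen=True)
class SplitSpec:
    """Hold-out and cross-validation layout."""

    test_fraction: float = 0.2
    cv_folds: int = 10
    shuffle: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValidationError("test_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValidationError("need at least 2 CV folds")


@dataclass(frozen=True)
class ModelGrid:
    """Hyper-parameter candidates per learner."""

    svr_c: tuple = (1.0, 10.0, 100.0)
    svr_gamma: tuple = ("scale", 0.01, 0.1)
    svr_epsilon: tuple = (0.1, 1.0)
    rf_n_trees: tuple = (100, 200, 250)
    rf_max_depth: tuple = (3, 5, 10, None)
    knn_k: tuple = (3, 4, 5, 6, 7)
    gnb_n_bins: tuple = (5,)

    def __post_init__(self) -> None:
        for name in ("svr_c", "svr_gamma", "svr_epsilon", "rf_n_trees",
                     "rf_max_depth", "knn_k", "gnb_n_bins"):
            if len(getattr(self, name)) == 0:
                raise ValidationError(f"{name}: candidate list may not be empty")
        if any(n < 100 or n > 250 for n in self.rf_n_trees):
            warnings.warn("forest sizes outside the 100-250 tree design range")


class GNBRegressor(BaseEstimator, RegressorMixin):
    """Discretized Gaussian naive-Bayes pseudo-regressor.

    Ages are discretized into ``n_bins`` equal-frequency bins (edges at
    empirical quantiles); a Gaussian NB classifier is fitted to the binned
    labels and its posterior is projected back to the continuous scale via
    the bin midpoints: ``prediction = sum_b P(b | x) * midpoint(b)`` with
    ``midpoint = (lower_edge + upper_edge) / 2``. Predictions therefore
    always lie inside ``[min midpoint, max midpoint]``.
    """

    def __init__(self, n_bins: int = 5, var_smoothing: float = 1e-9):
        self.n_bins = n_bins
        self.var_smoothing = var_smoothing

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")
        if self.n_bins > len(np.unique(y)):
            raise ValidationError(
                f"n_bins = {self.n_bins} exceeds the {len(np.unique(y))} distinct ages"
            )
        edges = np.quantile(y, np.linspace(0, 1, self.n_bins + 1))
        if len(np.unique(edges)) != len(edges):
            raise ValidationError("tied quantile edges: reduce n_bins")
        self.bin_edges_ = edges
        self.midpoints_ = (edges[:-1] + edges[1:]) / 2.0
        labels = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, self.n_bins - 1)
        self.gnb_ = GaussianNB(var_smoothing=self.var_smoothing)
        self.gnb_.fit(np.asarray(X, dtype=float), labels)
        return self

    def predict(self, X):
        proba = self.gnb_.predict_proba(np.asarray(X, dtype=float))
        return proba @ self.midpoints_[self.gnb_.classes_]


def _features(df: pd.DataFrame) -> pd.DataFrame:
    return df[list(VERTEBRAE)]


def make_split(cohort: pd.DataFrame, spec: SplitSpec | None = None):
    """Single shuffled hold-out split with ``|test| = round(fraction * n)``."""
    spec = spec or SplitSpec()
    n = len(cohort)
    if n < 10:
        raise ValidationError(f"cohort of {n} subjects is too small to split")
    n_test = int(round(spec.test_fraction * n))
    train, test = train_test_split(
        cohort, test_size=n_test, shuffle=spec.shuffle,
        random_state=spec.seed if spec.shuffle else None,
    )
    return train, test


def _make_estimator(model_name: str, grid: ModelGrid, seed: int):
    if model_name == "svr_rbf":
        est = SVR(kernel="rbf")
        params = {"model__C": grid.svr_c, "model__gamma": grid.svr_gamma,
                  "model__epsilon": grid.svr_epsilon}
    elif model_name == "svr_lin":
        est = SVR(kernel="linear")
        params = {"model__C": grid.svr_c, "model__epsilon": grid.svr_epsilon}
    elif model_name == "rf":
        est = RandomForestRegressor(bootstrap=True, oob_score=True, random_state=seed)
        params = {"model__n_estimators": grid.rf_n_trees,
                  "model__max_depth": grid.rf_max_depth}
    elif model_name == "knn":
        est = KNeighborsRegressor()
        params = {"model__n_neighbors": grid.knn_k}
    elif model_name == "gnb_reg":
        est = GNBRegressor()
        params = {"model__n_bins": grid.gnb_n_bins}
    else:
        raise ValidationError(f"unknown model {model_name!r}; choose from {MODEL_NAMES}")
    return Pipeline([("scale", StandardScaler()), ("model", est)]), params


def tune_model(train: pd.DataFrame, model_name: str,
               grid: ModelGrid | None = None,
               spec: SplitSpec | None = None):
    """Grid-search one learner by shuffled k-fold CV inside the training set.

    Standardization happens inside the pipeline, hence within each fold's
    training part only. Returns the refitted best pipeline and the winner's
    mean fold R2.
    """
    grid = grid or ModelGrid()
    spec = spec or SplitSpec()
    pipe, params = _make_estimator(model_name, grid, spec.seed)
    search = GridSearchCV(
        pipe, params, scoring="r2",
        cv=KFold(spec.cv_folds, shuffle=spec.shuffle, random_state=spec.seed),
        error_score="raise",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(_features(train), train["age"])
    return search.best_estimator_, float(search.best_score_)


@dataclass(frozen=True)
class EvalReport:
    """Hold-out metrics for one learner and sex."""

    model_name: str
    sex: str
    n_test: int
    k_predictors: int
    holdout_r2: float
    r2_ci_lo: float
    r2_ci_hi: float
    see_years: float
    see_ci_lo: float
    see_ci_hi: float
    mae_years: float
    rmse_years: float
    cv_r2: float = np.nan
    oob_r2: float = np.nan
    seed: int = 42

    def summary(self) -> str:
        lines = [
            f"{self.model_name} ({self.sex}): hold-out n = {self.n_test}",
            f"  R2    {self.holdout_r2:+.3f}  (95% CI {self.r2_ci_lo:+.2f} to {self.r2_ci_hi:+.2f})",
            f"  SEE   {self.see_years:.2f} y (95% CI {self.see_ci_lo:.1f} to {self.see_ci_hi:.1f})",
            f"  MAE   {self.mae_years:.2f} y   RMSE {self.rmse_years:.2f} y",
            f"  CV R2 {self.cv_r2:+.3f}" + (
                f"   OOB R2 {self.oob_r2:+.3f}" if np.isfinite(self.oob_r2) else ""),
        ]
        return "\n".join(lines)


def _see(residuals: np.ndarray, k: int, warn: bool = False) -> float:
    n = len(residuals)
    if warn and n <= k + 1:
        warnings.warn(f"SEE divisor n - k - 1 <= 0 for n = {n}, k = {k}; using max(1, .)")
    return float(np.sqrt(np.sum(residuals**2) / max(1, n - k - 1)))


def evaluate(model, test: pd.DataFrame, k_predictors: int = len(VERTEBRAE),
             model_name: str = "", sex: str = "", cv_r2: float = np.nan,
             n_boot: int = 1000, seed: int = 42) -> EvalReport:
    """Score a fitted model on the hold-out set.

    MAE, RMSE, R2 and the SEE (``k`` = number of retained predictors), with
    1000-resample percentile-bootstrap CIs for R2 and SEE. The out-of-bag R2
    is reported when the underlying estimator exposes one (random forest).
    """
    if len(test) == 0:
        raise ValidationError("empty test set")
    y = test["age"].to_numpy(dtype=float)
    pred = np.asarray(model.predict(_features(test)), dtype=float)
    resid = y - pred
    r2 = r2_score(y, pred)
    rng = np.random.default_rng(seed)
    r2_bs, see_bs = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, len(y), len(y))
        if np.ptp(y[idx]) == 0:
            continue
        r2_bs.append(r2_score(y[idx], pred[idx]))
        see_bs.append(_see(resid[idx], k_predictors))
    final = getattr(model, "named_steps", {}).get("model", model)
    oob = getattr(final, "oob_score_", np.nan)
    return EvalReport(
        model_name=model_name, sex=sex, n_test=len(y), k_predictors=k_predictors,
        holdout_r2=float(r2),
        r2_ci_lo=float(np.percentile(r2_bs, 2.5)), r2_ci_hi=float(np.percentile(r2_bs, 97.5)),
        see_years=_see(resid, k_predictors, warn=True),
        see_ci_lo=float(np.percentile(see_bs, 2.5)), see_ci_hi=float(np.percentile(see_bs, 97.5)),
        mae_years=float(mean_absolute_error(y, pred)),
        rmse_years=float(np.sqrt(np.mean(resid**2))),
        cv_r2=float(cv_r2), oob_r2=float(oob), seed=seed,
    )


def permutation_importance(model, test: pd.DataFrame, n_repeats: int = 20,
                           seed: int = 42) -> pd.Series:
    """Mean drop in hold-out R2 when each DS column is shuffled."""
    res = _sk_permutation_importance(
        model, _features(test), test["age"], scoring="r2",
        n_repeats=n_repeats, random_state=seed,
    )
    return pd.Series(res.importances_mean, index=list(VERTEBRAE))


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    loa_lo: float
    loa_hi: float
    sd_diff: float


def bland_altman(predictions, truths) -> BlandAltman:
    """Bias and 95% limits of agreement of prediction - truth differences."""
    pred = np.asarray(predictions, dtype=float)
    truth = np.asarray(truths, dtype=float)
    if pred.shape != truth.shape:
        raise ValidationError("prediction and truth vectors differ in length")
    if len(pred) < 2:
        raise ValidationError("need at least 2 paired values")
    d = pred - truth
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, loa_lo=bias - 1.96 * sd,
                       loa_hi=bias + 1.96 * sd, sd_diff=sd)


def learning_curve(model_name: str, train: pd.DataFrame,
                   fractions=(0.4, 0.6, 0.8, 1.0),
                   spec: SplitSpec | None = None,
                   grid: ModelGrid | None = None) -> pd.DataFrame:
    """Training and CV R2 of the tuned learner on seeded subsamples.

    For each fraction a subsample of the training set is drawn (seeded,
    without replacement), the learner re-tuned on it, and both the training
    R2 and the winner's CV R2 recorded. Fractions whose subsample is smaller
    than the fold count are skipped with a warning.
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValidationError("fractions must lie in (0, 1]")
        n_sub = int(round(frac * len(train)))
        if n_sub < spec.cv_folds:
            warnings.warn(f"fraction {frac}: subsample of {n_sub} < {spec.cv_folds} folds; skipped")
            continue
        sub = train if frac == 1.0 else train.iloc[
            rng.choice(len(train), size=n_sub, replace=False)]
        model, cv_r2 = tune_model(sub, model_name, grid=grid, spec=spec)
        train_r2 = r2_score(sub["age"], model.predict(_features(sub)))
        rows.append({"fraction": frac, "n": n_sub,
                     "train_r2": float(train_r2), "cv_r2": float(cv_r2)})
    return pd.DataFrame(rows)
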