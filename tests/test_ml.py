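"""Hold-out protocol, learners, GNB pseudo-regressor and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.ensemble import RandomForestRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

import vertds.ml as ml
from vertds.errors import ValidationError
from vertds.phantoms import VERTEBRAE


def _frame(ages, ds):
    data = {"subject_id": [f"s{i}" for i in range(len(ages))],
            "sex": ["M"] * len(ages), "age": np.asarray(ages, float)}
    for j, vert in enumerate(VERTEBRAE):
        data[vert] = ds[:, j]
    return pd.DataFrame(data)


def _informative_frame(n, seed, slopes=None, noise=0.15):
    rng = np.random.default_rng(seed)
    ages = rng.uniform(21, 94, n)
    slopes = np.zeros(19) if slopes is None else np.asarray(slopes, float)
    ds = 0.3 + ages[:, None] * slopes + rng.normal(0, noise, (n, 19))
    return _frame(ages, np.maximum(ds, 1e-6))


class TestSplit:
    def test_sizes_disjoint_exhaustive(self):
        df = _informative_frame(94, 0)
        train, test = ml.make_split(df, ml.SplitSpec(seed=42))
        assert len(test) == 19 and len(train) == 75
        assert set(train.index).isdisjoint(test.index)
        assert set(train.index) | set(test.index) == set(df.index)

    def test_seed_determinism(self):
        df = _informative_frame(60, 1)
        t1, _ = ml.make_split(df, ml.SplitSpec(seed=5))
        t2, _ = ml.make_split(df, ml.SplitSpec(seed=5))
        t3, _ = ml.make_split(df, ml.SplitSpec(seed=6))
        assert list(t1.index) == list(t2.index)
        assert list(t1.index) != list(t3.index)

    def test_too_small_rejected(self):
        with pytest.raises(ValidationError):
            ml.make_split(_informative_frame(8, 2))


class TestTuneModel:
    def test_single_candidate_selected(self):
        df = _informative_frame(60, 3, slopes=np.r_[np.zeros(18), 0.01])
        grid = ml.ModelGrid(knn_k=(4,))
        model, cv_r2 = ml.tune_model(df, "knn", grid=grid, spec=ml.SplitSpec(cv_folds=5))
        assert model.named_steps["model"].n_neighbors == 4
        assert np.isfinite(cv_r2)

    def test_duplicated_rows_make_knn3_perfect(self):
        base = _informative_frame(20, 4, slopes=np.full(19, 0.01), noise=0.0)
        df = pd.concat([base] * 4, ignore_index=True)  # 3 exact copies of each row
        model, cv_r2 = ml.tune_model(df, "knn", spec=ml.SplitSpec(cv_folds=5, seed=0))
        assert model.named_steps["model"].n_neighbors == 3
        assert cv_r2 > 0.95

    def test_unknown_model_rejected(self):
        with pytest.raises(ValidationError):
            ml.tune_model(_informative_frame(40, 5), "mlp")

    def test_fold_wise_standardization_differs_from_global(self):
        # leakage contract: z-scoring before CV uses test-fold information;
        # the pipeline must standardize within training folds only
        from sklearn.model_selection import KFold, cross_val_score
        from sklearn.svm import SVR

        rng = np.random.default_rng(6)
        n = 60
        ages = np.r_[rng.uniform(25, 45, n // 2), rng.uniform(70, 90, n // 2)]
        ds = 0.3 + 0.01 * ages[:, None] + rng.normal(0, 0.05, (n, 19))
        df = _frame(ages, ds)
        X, y = df[list(VERTEBRAE)], df["age"]
        cv = KFold(5)  # unshuffled: folds are mean-shifted blocks
        pipe = Pipeline([("scale", StandardScaler()), ("model", SVR(kernel="rbf"))])
        honest = cross_val_score(pipe, X, y, cv=cv, scoring="r2")
        Xg = StandardScaler().fit_transform(X)  # leaky global standardization
        leaky = cross_val_score(SVR(kernel="rbf"), Xg, y, cv=cv, scoring="r2")
        assert not np.allclose(honest, leaky)


class TestGNBRegressor:
    def test_single_bin_constant_midrange(self):
        y = np.array([20.0, 30.0, 50.0, 80.0])
        X = np.arange(8.0).reshape(4, 2)
        model = ml.GNBRegressor(n_bins=1).fit(X, y)
        np.testing.assert_allclose(model.predict(X), 50.0)  # (20 + 80) / 2

    def test_symmetric_posterior_averages_midpoints(self):
        # identical feature distributions in both bins -> posterior 0.5/0.5
        y = np.array([20.0, 30.0, 60.0, 70.0])
        X = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        model = ml.GNBRegressor(n_bins=2).fit(X, y)
        mids = model.midpoints_
        np.testing.assert_allclose(model.predict([[0.0]]), mids.mean(), atol=1e-9)

    def test_separable_clusters_hit_bin_midpoints(self):
        rng = np.random.default_rng(7)
        y = np.r_[rng.uniform(25, 30, 40), rng.uniform(75, 80, 40)]
        X = np.r_[rng.normal(0, 0.1, (40, 3)), rng.normal(5, 0.1, (40, 3))]
        model = ml.GNBRegressor(n_bins=2).fit(X, y)
        pred = model.predict(X)
        assert np.all(np.abs(pred[:40] - model.midpoints_[0]) < 1.0)
        assert np.all(np.abs(pred[40:] - model.midpoints_[1]) < 1.0)

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValidationError):
            ml.GNBRegressor(n_bins=5).fit(np.zeros((4, 2)), [1.0, 1.0, 2.0, 2.0])

    @given(st.integers(0, 500))
    def test_predictions_bounded_by_midpoints(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(20, 90, 40)
        X = rng.normal(size=(40, 4))
        model = ml.GNBRegressor(n_bins=4).fit(X, y)
        pred = model.predict(rng.normal(size=(20, 4)) * 3)
        assert np.all(pred >= model.midpoints_.min() - 1e-9)
        assert np.all(pred <= model.midpoints_.max() + 1e-9)


class _Identity:
    def predict(self, X):
        return np.asarray(X)[:, 15] * 100  # L3 * 100


class TestEvaluate:
    def test_perfect_predictions(self):
        df = _informative_frame(30, 8)
        df["L3"] = df["age"] / 100
        rep = ml.evaluate(_Identity(), df, k_predictors=1, n_boot=50)
        assert rep.mae_years == pytest.approx(0, abs=1e-9)
        assert rep.rmse_years == pytest.approx(0, abs=1e-9)
        assert rep.holdout_r2 == pytest.approx(1.0)

    def test_constant_predictor_nonpositive_r2(self):
        class Mean:
            def predict(self, X):
                return np.full(len(X), 57.0)

        rep = ml.evaluate(Mean(), _informative_frame(30, 9), n_boot=50)
        assert rep.holdout_r2 <= 0

    def test_see_rmse_arithmetic(self):
        # residuals (1, -1, 2, -2): RMSE = sqrt(2.5), SEE = sqrt(10 / 2) for k=1
        y = np.array([50.0, 60.0, 70.0, 80.0])
        pred = y - np.array([1.0, -1.0, 2.0, -2.0])
        df = _frame(y, np.full((4, 19), 0.5))

        class Fixed:
            def predict(self, X):
                return pred

        rep = ml.evaluate(Fixed(), df, k_predictors=1, n_boot=10)
        assert rep.rmse_years == pytest.approx(np.sqrt(2.5))
        assert rep.see_years == pytest.approx(np.sqrt(10 / 2))
        assert rep.rmse_years >= rep.mae_years

    def test_bootstrap_ci_brackets_point_estimate(self):
        df = _informative_frame(40, 10, slopes=np.full(19, 0.008), noise=0.1)
        model, cv = ml.tune_model(df, "knn", grid=ml.ModelGrid(knn_k=(5,)),
                                  spec=ml.SplitSpec(cv_folds=5))
        rep = ml.evaluate(model, df, cv_r2=cv)
        assert rep.r2_ci_lo <= rep.holdout_r2 <= rep.r2_ci_hi
        assert rep.see_ci_lo <= rep.see_years <= rep.see_ci_hi

    def test_oob_reported_for_forest_only(self):
        df = _informative_frame(80, 11, slopes=np.full(19, 0.01))
        train, test = ml.make_split(df)
        grid = ml.ModelGrid(rf_n_trees=(100,), rf_max_depth=(5,), knn_k=(5,))
        rf, _ = ml.tune_model(train, "rf", grid=grid)
        knn, _ = ml.tune_model(train, "knn", grid=grid)
        assert np.isfinite(ml.evaluate(rf, test, n_boot=20).oob_r2)
        assert np.isnan(ml.evaluate(knn, test, n_boot=20).oob_r2)


class TestDiagnostics:
    def test_permutation_importance_ranks_informative_feature(self):
        df = _informative_frame(200, 12, slopes=np.r_[np.zeros(15), 0.02,
                                                      np.zeros(3)], noise=0.05)
        train, test = ml.make_split(df)
        pipe = Pipeline([("scale", StandardScaler()),
                         ("model", RandomForestRegressor(100, random_state=0))])
        pipe.fit(train[list(VERTEBRAE)], train["age"])
        imp = ml.permutation_importance(pipe, test, n_repeats=10, seed=0)
        assert imp.idxmax() == "L3"
        assert imp.drop("L3").abs().max() < imp["L3"] / 2

    def test_dominant_l3_ranks_first_across_seeds(self):
        first = 0
        n_seeds = 15
        for seed in range(n_seeds):
            df = _informative_frame(150, 100 + seed,
                                    slopes=np.r_[np.zeros(15), 0.02, np.zeros(3)],
                                    noise=0.1)
            train, test = ml.make_split(df, ml.SplitSpec(seed=seed))
            pipe = Pipeline([("scale", StandardScaler()),
                             ("model", RandomForestRegressor(80, random_state=seed))])
            pipe.fit(train[list(VERTEBRAE)], train["age"])
            imp = ml.permutation_importance(pipe, test, n_repeats=5, seed=seed)
            first += imp.idxmax() == "L3"
        assert first >= 0.9 * n_seeds

    def test_bland_altman_arithmetic(self):
        truth = np.array([50.0, 60.0, 70.0])
        ba = ml.bland_altman(truth, truth)
        assert ba.bias == 0 and ba.loa_lo == 0 and ba.loa_hi == 0
        ba = ml.bland_altman(truth + 5, truth)
        assert ba.bias == pytest.approx(5) and ba.loa_hi == pytest.approx(5)
        ba = ml.bland_altman(truth + [-2, 0, 2], truth)
        assert ba.bias == pytest.approx(0)
        assert ba.loa_hi == pytest.approx(1.96 * 2)
        with pytest.raises(ValidationError):
            ml.bland_altman([1.0], [1.0])

    def test_learning_curve_contracts(self):
        df = _informative_frame(100, 13, slopes=np.full(19, 0.01), noise=0.1)
        grid = ml.ModelGrid(rf_n_trees=(100,), rf_max_depth=(None,))
        spec = ml.SplitSpec(cv_folds=5, seed=0)
        lc = ml.learning_curve("rf", df, fractions=(0.5, 1.0), spec=spec, grid=grid)
        # fraction 1.0 reproduces tune_model's cv_r2
        _, cv_full = ml.tune_model(df, "rf", grid=grid, spec=spec)
        row = lc[lc["fraction"] == 1.0].iloc[0]
        assert row["cv_r2"] == pytest.approx(cv_full)
        # a memorizing forest trains better than it cross-validates
        assert (lc["train_r2"] >= lc["cv_r2"]).all()

    def test_learning_curve_skips_tiny_fraction(self):
        df = _informative_frame(40, 14, slopes=np.full(19, 0.01))
        with pytest.warns(UserWarning, match="skipped"):
            lc = ml.learning_curve("knn", df, fractions=(0.05, 1.0),
                                   spec=ml.SplitSpec(cv_folds=5),
                                   grid=ml.ModelGrid(knn_k=(3,)))
        assert list(lc["fraction"]) == [1.0]
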