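"""UPLS calibration: matrix assembly, autoscaling, NIPALS, CV, diagnostics."""

import warnings

import numpy as np
import pytest

import eemviab as ev
from eemviab.calibration import (
    dose_mean_response,
    venetian_blind_folds,
)
from eemviab.eem import GeometryError

from conftest import make_eem


def random_problem(rng, n=10, p=3):
    X = rng.standard_normal((n, p))
    y = rng.standard_normal(n)
    return X - X.mean(axis=0), y - y.mean()


class TestAssembleAndSplit:
    def test_default_dataset_assembles_to_72x1340(self, default_dataset):
        matrix = ev.assemble_matrix(default_dataset.eems)
        assert matrix.values.shape == (72, 1340)
        assert matrix.columns.shape == (1340, 2)

    def test_single_eem(self, geometry):
        matrix = ev.assemble_matrix([make_eem(geometry)])
        assert matrix.values.shape == (1, 1340)

    def test_empty_and_mixed_geometry_rejected(self, geometry):
        with pytest.raises(ValueError):
            ev.assemble_matrix([])
        other = ev.AcquisitionGeometry(ex_stop=490)
        with pytest.raises(GeometryError):
            ev.assemble_matrix([make_eem(geometry), make_eem(other)])

    def test_split_sizes_disjoint_and_deterministic(self, default_dataset):
        matrix = ev.assemble_matrix(default_dataset.eems)
        spec = ev.SplitSpec(train_fraction=0.75, seed=3)
        s1 = ev.split_train_test(matrix, spec)
        s2 = ev.split_train_test(matrix, spec)
        assert s1.train.n_samples == 54 and s1.test.n_samples == 18
        assert np.array_equal(s1.train_indices, s2.train_indices)
        assert len(np.intersect1d(s1.train_indices, s1.test_indices)) == 0
        assert len(np.union1d(s1.train_indices, s1.test_indices)) == 72

    def test_small_even_split(self, geometry):
        matrix = ev.assemble_matrix([make_eem(geometry) for _ in range(4)])
        s = ev.split_train_test(matrix, ev.SplitSpec(train_fraction=0.5, seed=0))
        assert s.train.n_samples == 2 and s.test.n_samples == 2

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            ev.SplitSpec(train_fraction=1.0)


class TestAutoscale:
    def test_apply_to_self_standardizes(self, rng):
        X = rng.uniform(0, 10, size=(20, 7))
        params = ev.autoscale_fit(X)
        Xs = ev.autoscale_apply(X, params)
        assert np.allclose(Xs.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(Xs.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_hand_example(self):
        X = np.array([[1.0], [3.0]])
        params = ev.autoscale_fit(X)
        assert params.mean[0] == 2.0
        assert params.sd[0] == pytest.approx(np.sqrt(2))
        Xs = ev.autoscale_apply(X, params)
        assert Xs[:, 0] == pytest.approx([-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_constant_column_scaled_to_zero_with_warning(self, rng):
        X = np.column_stack([rng.standard_normal(10), np.full(10, 4.2)])
        params = ev.autoscale_fit(X)
        assert list(params.zero_variance) == [False, True]
        with pytest.warns(UserWarning, match="zero-variance"):
            Xs = ev.autoscale_apply(X, params)
        assert np.all(Xs[:, 1] == 0.0)

    def test_column_mismatch_rejected(self, rng):
        params = ev.autoscale_fit(rng.standard_normal((5, 3)))
        with pytest.raises(ValueError):
            ev.autoscale_apply(rng.standard_normal((5, 4)), params)


class TestNIPALS:
    def test_rank_one_exact_fit(self, rng):
        t = rng.standard_normal(12)
        p = rng.standard_normal(5)
        X = np.outer(t, p)
        y = 2.0 * t
        core = ev.fit_pls(X, y, n_lv=1)
        assert np.allclose(X @ core.coef, y, atol=1e-8)

    def test_full_rank_matches_normal_equations(self, rng):
        """With n_lv = rank, the PLS coefficient equals ordinary least squares."""
        for _ in range(20):
            X, y = random_problem(rng)
            core = ev.fit_pls(X, y, n_lv=3)
            b_ols = np.linalg.solve(X.T @ X, X.T @ y)
            assert np.allclose(core.coef, b_ols, atol=1e-8)

    def test_scores_orthogonal_and_weights_unit_norm(self, rng):
        X, y = random_problem(rng, n=30, p=8)
        core = ev.fit_pls(X, y, n_lv=5)
        gram = core.scores.T @ core.scores
        off_diag = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off_diag)) < 1e-8
        assert np.allclose(np.linalg.norm(core.weights, axis=0), 1.0)

    def test_orthogonal_response_stops_early(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to both columns
        with pytest.warns(UserWarning, match="stopping early"):
            core = ev.fit_pls(X, y, n_lv=2)
        assert core.n_lv == 0
        assert np.all(core.coef == 0.0)

    def test_n_lv_out_of_range_rejected(self, rng):
        X, y = random_problem(rng)
        with pytest.raises(ValueError):
            ev.fit_pls(X, y, n_lv=0)
        with pytest.raises(ValueError):
            ev.fit_pls(X, y, n_lv=4)

    def test_matches_sklearn_pls_regression(self, rng):
        """Independent cross-check against scikit-learn's PLS implementation."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        for n_lv in (1, 2, 3):
            X, y = random_problem(rng, n=15, p=6)
            core = ev.fit_pls(X, y, n_lv=n_lv)
            ref = sklearn_pls.PLSRegression(n_components=n_lv, scale=False).fit(X, y)
            assert np.allclose(core.coef, ref.coef_.ravel(), atol=1e-8)


class TestCrossValidation:
    def test_venetian_blind_fold_pattern(self):
        folds = venetian_blind_folds(6, 3)
        assert [list(f) for f in folds] == [[0, 3], [1, 4], [2, 5]]

    def test_fewer_rows_than_folds_rejected(self):
        with pytest.raises(ValueError):
            venetian_blind_folds(2, 3)

    def test_rmsecv_curve_finite_nonnegative(self, rng):
        X = rng.standard_normal((24, 6))
        y = X[:, 0] + 0.1 * rng.standard_normal(24)
        cv = ev.cross_validate(X, y, max_lv=4, n_splits=4)
        assert cv.rmsecv.shape == (5,)
        assert np.all(np.isfinite(cv.rmsecv)) and np.all(cv.rmsecv >= 0)
        assert cv.rmsecv[cv.n_lv] == cv.rmsecv.min()

    def test_noise_free_rank_one_selects_one_lv(self, rng):
        t = rng.standard_normal(20)
        X = np.outer(t, rng.standard_normal(5))
        y = 3.0 * t + 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # deflated X is rank-deficient
            cv = ev.cross_validate(X, y, max_lv=3, n_splits=5)
        assert cv.n_lv == 1
        assert cv.rmsecv[1] == pytest.approx(0.0, abs=1e-8)

    def test_zero_lv_rmsecv_is_pooled_mean_model_error(self, rng):
        """The 0-LV entry is the RMS error of each fold's retained-row mean."""
        X = rng.standard_normal((12, 4))
        y = rng.uniform(0, 100, 12)
        cv = ev.cross_validate(X, y, max_lv=2, n_splits=3)
        sq = 0.0
        for held in venetian_blind_folds(12, 3):
            keep = np.setdiff1d(np.arange(12), held)
            sq += np.sum((y[held] - y[keep].mean()) ** 2)
        assert cv.rmsecv[0] == pytest.approx(np.sqrt(sq / 12))


class TestPredictAndDiagnostics:
    def test_training_prediction_reproduces_rank_one_response(self, rng):
        t = rng.standard_normal(16)
        X = np.outer(t, rng.standard_normal(6)) + 5.0
        y = 40.0 + 10.0 * t
        matrix = ev.DataMatrix(
            values=X,
            meta=__import__("pandas").DataFrame({"sample_id": [str(i) for i in range(16)],
                                                 "dose_min": 0.0, "replicate": 0}),
            columns=np.zeros((6, 2)),
            geometry=ev.AcquisitionGeometry(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ev.fit_upls(matrix, y, max_lv=2, n_splits=4)
        assert np.allclose(model.predict_values(X), y, atol=1e-6)

    def test_prediction_invariant_to_consistent_column_rescaling(self, rng):
        """Autoscaling absorbs any per-column affine rescaling of the data."""
        X_train = rng.standard_normal((20, 5))
        X_test = rng.standard_normal((8, 5))
        y = rng.uniform(0, 100, 20)
        scale = rng.uniform(0.5, 3.0, 5)
        offset = rng.uniform(-10, 10, 5)

        def fit_predict(train, test):
            params = ev.autoscale_fit(train)
            core = ev.fit_pls(ev.autoscale_apply(train, params), y - y.mean(), 3)
            return ev.autoscale_apply(test, params) @ core.coef + y.mean()

        p_raw = fit_predict(X_train, X_test)
        p_scaled = fit_predict(X_train * scale + offset, X_test * scale + offset)
        assert np.allclose(p_raw, p_scaled, atol=1e-8)

    @pytest.mark.parametrize(
        "transform, expected",
        [(lambda x: x, (1.0, 0.0, 1.0)), (lambda x: 2 * x + 3, (2.0, 3.0, 1.0))],
    )
    def test_perfect_linear_fits(self, transform, expected):
        x = np.array([10.0, 30.0, 50.0, 90.0])
        fit = ev.linear_fit_diagnostics(transform(x), x)
        assert (fit.slope, fit.intercept, fit.r_squared) == pytest.approx(expected)
        assert fit.ci_half_slope == pytest.approx(0.0, abs=1e-8)

    def test_hand_ols_example(self):
        fit = ev.linear_fit_diagnostics(
            predicted=np.array([1.0, 1.0, 3.0, 3.0]), reference=np.array([0.0, 1.0, 2.0, 3.0])
        )
        assert fit.slope == pytest.approx(0.8)
        assert fit.intercept == pytest.approx(0.8)
        assert fit.r_squared == pytest.approx(0.8)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ev.linear_fit_diagnostics(np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0]))

    def test_aggregate_by_dose(self):
        preds = np.array([40.0, 60.0, 10.0, 10.0])
        doses = np.array([20, 20, 40, 40])
        out = ev.aggregate_by_dose(preds, doses)
        row20 = out[out["dose_min"] == 20].iloc[0]
        assert row20["mean"] == 50.0
        assert row20["sd"] == pytest.approx(np.sqrt(200))
        assert out["n"].sum() == 4
        row40 = out[out["dose_min"] == 40].iloc[0]
        assert row40["sd"] == 0.0

    def test_aggregate_single_sample_dose_warns(self):
        with pytest.warns(UserWarning, match="single sample"):
            out = ev.aggregate_by_dose(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 10]))
        assert np.isnan(out.loc[out["dose_min"] == 10, "sd"]).all()

    def test_dose_mean_response_lookup(self, default_dataset):
        matrix = ev.assemble_matrix(default_dataset.eems[:5])
        y = dose_mean_response(matrix, default_dataset.mtt_table)
        expected = default_dataset.mtt_values(0.0).mean()
        assert np.allclose(y, expected)
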