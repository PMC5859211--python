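import numpy as np
import pytest

from beanspec.calibration import (
    _rmse,
    compute_metrics,
    cross_validate,
    detect_outliers,
    fit_mlr,
    fit_pls,
    predict,
)
from beanspec.synthetic import SceneSpec, generate_calibration_table


def random_instance(n=10, p=4, seed=0, noise=0.05):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(0, noise, n)
    return X, y


class TestFitPLS:
    def test_rank_one_recovered_with_single_lv(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(size=6)
        t = rng.normal(size=12)
        X = np.outer(t, direction)
        y = 2.0 * t + 1.0
        model = fit_pls(X, y, n_lv=1)
        np.testing.assert_allclose(model.fitted_values, y, atol=1e-10)

    def test_full_lv_matches_least_squares_oracle(self):
        """At full rank PLS spans the whole X space and agrees with OLS."""
        X, y = random_instance()
        model = fit_pls(X, y, n_lv=4)
        A = np.column_stack([np.ones(len(X)), X])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        np.testing.assert_allclose(model.fitted_values, A @ coef, atol=1e-8)

    def test_matches_sklearn_pls(self):
        """Independent cross-check against sklearn's PLS at partial LV."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = random_instance(n=30, p=12, seed=3)
        model = fit_pls(X, y, n_lv=5)
        sk = PLSRegression(n_components=5, scale=False).fit(X, y)
        np.testing.assert_allclose(
            model.fitted_values, sk.predict(X).ravel(), atol=1e-8
        )

    def test_beta_form_equals_factor_form(self):
        X, y = random_instance(n=25, p=15, seed=2)
        model = fit_pls(X, y, n_lv=6)
        T = model.scores(X)
        factor_pred = model.y_mean + T @ model.y_loadings
        np.testing.assert_allclose(model.fitted_values, factor_pred, atol=1e-10)

    def test_response_shift_moves_intercept_only(self):
        X, y = random_instance(seed=5)
        m1 = fit_pls(X, y, 3)
        m2 = fit_pls(X, y + 7.5, 3)
        np.testing.assert_allclose(m1.beta, m2.beta, atol=1e-12)
        np.testing.assert_allclose(m2.fitted_values, m1.fitted_values + 7.5, atol=1e-10)

    def test_invalid_inputs(self):
        X, y = random_instance()
        with pytest.raises(ValueError):
            fit_pls(X, y, n_lv=0)
        with pytest.raises(ValueError):
            fit_pls(X, y, n_lv=40)
        with pytest.raises(ValueError):
            fit_pls(X, np.ones(len(y)), n_lv=2)


class TestPredict:
    def test_calibration_set_reproduces_fitted_values(self):
        X, y = random_instance()
        model = fit_pls(X, y, 3)
        np.testing.assert_allclose(predict(model, X), model.fitted_values)

    def test_single_spectrum_equals_batch_row(self):
        X, y = random_instance()
        model = fit_pls(X, y, 3)
        np.testing.assert_allclose(predict(model, X[4]), predict(model, X)[4])

    def test_wavelength_axis_mismatch(self):
        X, y = random_instance()
        model = fit_pls(X, y, 2, wavelengths=np.arange(4.0))
        with pytest.raises(ValueError):
            predict(model, X, wavelengths=np.arange(4.0) + 1)
        with pytest.raises(ValueError):
            predict(model, X[:, :3])

    def test_noiseless_beans_recovered(self, lib256):
        spec = SceneSpec(noise_sd=0, scatter_slope_sd=0, scatter_offset_sd=0)
        table = generate_calibration_table(80, spec=spec, lib=lib256, seed=9)
        y = table.y("moisture_pct")
        model = fit_pls(table.X, y, n_lv=4, wavelengths=table.wavelengths)
        np.testing.assert_allclose(predict(model, table.X), y, atol=0.01)


class TestCrossValidate:
    def test_perfect_linear_response_gives_zero_rmsecv(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + 2.0
        per_lv, model = cross_validate(X, y, None, max_lv=6, seed=0)
        assert model.metrics.rmsecv < 1e-8

    def test_constant_residual_rmse(self):
        y = np.arange(10.0)
        assert _rmse(y, y + 0.3) == pytest.approx(0.3)
        assert _rmse(y, y - 0.3) == pytest.approx(0.3)

    def test_rmsecv_not_below_rmsec_typically(self, lib256):
        """Held-out error exceeds resubstitution error in the typical case."""
        wins = 0
        for rep in range(10):
            table = generate_calibration_table(60, lib=lib256, seed=300 + rep)
            _, model = cross_validate(table.X, table.y("moisture_pct"), "snv",
                                      max_lv=6, seed=rep)
            if model.metrics.rmsecv >= model.metrics.rmsec:
                wins += 1
        assert wins >= 8

    def test_seed_fixes_segments(self, lib256):
        table = generate_calibration_table(50, lib=lib256, seed=12)
        y = table.y("moisture_pct")
        m1 = cross_validate(table.X, y, "snv", max_lv=4, seed=7)[1].metrics
        m2 = cross_validate(table.X, y, "snv", max_lv=4, seed=7)[1].metrics
        assert m1.rmsecv == m2.rmsecv
        m3 = cross_validate(table.X, y, "snv", max_lv=4, seed=8)[1].metrics
        # different segmentation perturbs RMSECV only mildly
        assert abs(m3.rmsecv - m1.rmsecv) / m1.rmsecv < 0.10

    def test_max_lv_truncated_with_warning(self):
        X, y = random_instance(n=12, p=8, seed=6)
        with pytest.warns(UserWarning, match="truncated"):
            per_lv, model = cross_validate(X, y, None, max_lv=11, n_segments=4, seed=0)
        assert len(per_lv) <= 8

    def test_leave_one_out(self):
        X, y = random_instance(n=12, p=3, seed=8, noise=0.01)
        per_lv, model = cross_validate(X, y, None, max_lv=3, leave_one_out=True)
        assert model.metrics.rmsecv < 0.1


class TestComputeMetrics:
    @pytest.mark.parametrize("sd,rmsecv,printed,digits", [
        (0.79, 0.276, 2.9, 1),
        (10.77, 1.999, 5.4, 1),
        (2.64, 0.904, 2.92, 2),
        (3.10, 0.985, 3.15, 2),
    ])
    def test_rpd_worked_examples(self, sd, rmsecv, printed, digits):
        """RPD = SD(reference) / RMSECV for the published working points."""
        n = 200
        base = np.linspace(-1, 1, n)
        y = 10.0 + base / base.std(ddof=1) * sd  # exact ddof=1 SD
        resid = np.where(np.arange(n) % 2 == 0, rmsecv, -rmsecv)  # exact RMSE
        metrics = compute_metrics(y, y, y + resid)
        assert metrics.rpd == pytest.approx(sd / rmsecv, rel=1e-12)
        assert round(metrics.rpd, digits) == printed

    def test_perfect_prediction_panel(self):
        y = np.array([1.0, 2.0, 4.0, 7.0])
        m = compute_metrics(y, y, y)
        assert m.r2_cal == pytest.approx(1.0)
        assert m.rmsec == 0.0
        assert m.slope_cal == pytest.approx(1.0)
        assert m.offset_cv == pytest.approx(0.0, abs=1e-12)

    def test_rpd_identity_against_panel(self):
        rng = np.random.default_rng(0)
        y = rng.normal(10, 2, 50)
        ycv = y + rng.normal(0, 0.5, 50)
        m = compute_metrics(y, y, ycv)
        assert abs(m.rpd - np.std(y, ddof=1) / m.rmsecv) < 1e-12

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            compute_metrics([1.0, 2.0], [1.0, 2.0], [1.0, 2.0])


class TestMLR:
    def test_single_column_exact(self):
        x = np.linspace(0, 1, 10)[:, None]
        y = 2.0 * x.ravel() + 1.0
        model = fit_mlr(x, y)
        assert model.coef[0] == pytest.approx(2.0)
        assert model.intercept == pytest.approx(1.0)

    def test_equals_full_lv_pls(self):
        X, y = random_instance()
        mlr = fit_mlr(X, y)
        pls = fit_pls(X, y, n_lv=4)
        np.testing.assert_allclose(mlr.fitted_values, pls.fitted_values, atol=1e-8)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_mlr(X, rng.normal(size=20))

    def test_too_many_columns(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            fit_mlr(rng.normal(size=(6, 5)), rng.normal(size=6))


class TestOutliers:
    def test_clean_tables_mostly_unflagged(self, lib256):
        clean_runs = 0
        for rep in range(10):
            table = generate_calibration_table(80, lib=lib256, seed=700 + rep)
            y = table.y("moisture_pct")
            _, model = cross_validate(table.X, y, "snv", max_lv=5, seed=rep)
            Xp = model.chain.transform(table.X)
            if detect_outliers(model, Xp, y).size == 0:
                clean_runs += 1
        assert clean_runs >= 7

    def test_gross_reference_error_flagged(self, lib256):
        table = generate_calibration_table(80, lib=lib256, seed=42)
        y = table.y("moisture_pct").copy()
        y[17] += 10 * y.std(ddof=1)
        _, model = cross_validate(table.X, y, "snv", max_lv=5, seed=1)
        Xp = model.chain.transform(table.X)
        assert 17 in detect_outliers(model, Xp, y)

    def test_duplicate_rows_get_identical_flags(self, lib256):
        table = generate_calibration_table(40, lib=lib256, seed=77)
        X = np.vstack([table.X, table.X[5]])
        y = np.append(table.y("moisture_pct"), table.y("moisture_pct")[5])
        _, model = cross_validate(X, y, None, max_lv=4, seed=2)
        Xp = model.chain.transform(X)
        idx = set(detect_outliers(model, Xp, y))
        assert (5 in idx) == (len(y) - 1 in idx)
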