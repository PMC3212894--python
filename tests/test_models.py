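import numpy as np
import pandas as pd
import pytest

from stratiforest import fit_model, lasso_screen, predict_cells, sample_efficiency
from stratiforest.models import pearson_normality_test


def make_design(n, p, rng):
    return pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)])


class TestLassoScreen:
    def test_recovers_single_true_predictor(self):
        successes = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = make_design(200, 21, rng)
            y = 2.0 * X["x0"].to_numpy() + rng.normal(0, 0.05, 200)
            selected, lam = lasso_screen(X, y, folds=10, seed=seed)
            if "x0" in selected and len(selected) <= 5:
                successes += 1
            assert lam >= 0
        assert successes >= 4

    def test_pure_noise_empty_selection(self):
        import warnings as _warnings

        hits = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = make_design(100, 10, rng)
            y = rng.normal(size=100)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                selected, _ = lasso_screen(X, y, folds=5, seed=seed)
            hits.append(len(selected))
        assert np.median(hits) == 0

    def test_duplicated_column_one_selected(self, rng):
        X = make_design(150, 5, rng)
        X["dup"] = X["x0"]
        y = 3.0 * X["x0"].to_numpy() + rng.normal(0, 0.1, 150)
        selected, _ = lasso_screen(X, y, folds=5, seed=0)
        assert not {"x0", "dup"}.issubset(set(selected))
        assert {"x0", "dup"} & set(selected)

    def test_input_validation(self, rng):
        X = make_design(5, 2, rng)
        with pytest.raises(ValueError):
            lasso_screen(X, np.zeros(5), folds=10)


class TestFitModel:
    def test_noiseless_log_identity(self, rng):
        x = rng.normal(size=100)
        y = np.exp(1.0 + 0.5 * x)
        spec = fit_model(pd.DataFrame({"x": x}), y, transform="ln")
        assert spec.intercept == pytest.approx(1.0, abs=1e-10)
        assert spec.coefficients["x"] == pytest.approx(0.5, abs=1e-10)
        assert spec.r_squared == pytest.approx(1.0, abs=1e-10)
        assert spec.ln_offset == 0.0

    def test_zero_response_gets_offset(self, rng):
        x = rng.normal(size=50)
        y = np.clip(np.exp(x) - 1.0, 0.0, None)
        spec = fit_model(pd.DataFrame({"x": x}), y, transform="ln")
        assert spec.ln_offset == 1.0

    def test_logistic_half_proportion_zero_intercept(self):
        y = np.full(30, 0.5)
        spec = fit_model(pd.DataFrame(index=range(30)), y, transform="logit")
        assert spec.intercept == pytest.approx(0.0, abs=1e-6)

    def test_singular_design_reports_collinear_pair(self, rng):
        x = rng.normal(size=40)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            fit_model(X, np.exp(x), transform="ln")

    def test_residuals_orthogonal_to_predictors(self, rng):
        X = make_design(200, 4, rng)
        y = np.exp(0.3 * X["x0"].to_numpy() + 0.1 * X["x1"].to_numpy() + rng.normal(0, 0.2, 200))
        spec = fit_model(X, y, transform="ln")
        eta = spec.intercept + sum(
            spec.coefficients[c] * X[c].to_numpy() for c in spec.predictors
        )
        resid = np.log(y) - eta
        for c in X.columns:
            assert abs(np.dot(resid, X[c] - X[c].mean())) < 1e-8

    def test_coefficient_ci_coverage(self):
        # 95% CIs from the post-selection OLS cover the truth ~95% of the time
        covered = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=120)
            y = np.exp(0.8 + 0.5 * x + rng.normal(0, 0.3, 120))
            import statsmodels.api as sm

            res = sm.OLS(np.log(y), sm.add_constant(x)).fit()
            lo, hi = res.conf_int(alpha=0.05)[1]
            covered += lo <= 0.5 <= hi
        assert covered / reps >= 0.93

    def test_normality_stat_reported(self, rng):
        x = rng.normal(size=200)
        y = np.exp(1.0 + 0.5 * x + rng.normal(0, 0.2, 200))
        spec = fit_model(pd.DataFrame({"x": x}), y, transform="ln")
        assert np.isfinite(spec.normality_stat)
        assert 0.0 <= spec.normality_p <= 1.0


class TestPredictCells:
    def test_intercept_only_constant(self):
        spec = fit_model(pd.DataFrame(index=range(20)), np.full(20, np.exp(3.0)), transform="ln")
        cells = pd.DataFrame({"anything": np.arange(5.0)})
        np.testing.assert_allclose(predict_cells(spec, cells), np.exp(3.0), rtol=1e-10)

    def test_bias_correction_factor(self, rng):
        x = rng.normal(size=100)
        y = np.exp(1.0 + 0.5 * x + rng.normal(0, 0.4, 100))
        spec_off = fit_model(pd.DataFrame({"x": x}), y, transform="ln", bias_correction=False)
        spec_on = fit_model(pd.DataFrame({"x": x}), y, transform="ln", bias_correction=True)
        cells = pd.DataFrame({"x": rng.normal(size=10)})
        ratio = predict_cells(spec_on, cells) / predict_cells(spec_off, cells)
        np.testing.assert_allclose(ratio, np.exp(spec_on.residual_sd**2 / 2.0), rtol=1e-12)

    def test_bias_correction_reduces_mean_bias(self):
        # paired simulation: corrected back-transform is nearer the truth mean
        diffs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=150)
            sigma = 0.5
            y = np.exp(1.0 + 0.4 * x + rng.normal(0, sigma, 150))
            spec_off = fit_model(pd.DataFrame({"x": x}), y, transform="ln", bias_correction=False)
            spec_on = fit_model(pd.DataFrame({"x": x}), y, transform="ln", bias_correction=True)
            xs = rng.normal(size=300)
            cells = pd.DataFrame({"x": xs})
            truth_mean = np.mean(np.exp(1.0 + 0.4 * xs) * np.exp(sigma**2 / 2))
            bias_off = abs(predict_cells(spec_off, cells).mean() - truth_mean)
            bias_on = abs(predict_cells(spec_on, cells).mean() - truth_mean)
            diffs.append(bias_on < bias_off)
        assert np.mean(diffs) > 0.7

    def test_missing_predictor_named(self, rng):
        x = rng.normal(size=30)
        spec = fit_model(pd.DataFrame({"x": x}), np.exp(x), transform="ln")
        with pytest.raises(KeyError, match="x"):
            predict_cells(spec, pd.DataFrame({"other": np.zeros(3)}))

    def test_logistic_predictions_percent_scale(self, rng):
        x = rng.normal(size=100)
        p = 1 / (1 + np.exp(-(0.5 + x)))
        spec = fit_model(pd.DataFrame({"x": x}), 100 * p, transform="logit")
        preds = predict_cells(spec, pd.DataFrame({"x": x}))
        assert ((preds >= 0) & (preds <= 100)).all()
        assert np.corrcoef(preds, 100 * p)[0, 1] > 0.99

    def test_monotone_in_positive_predictor(self, rng):
        x = rng.normal(size=100)
        y = np.exp(1.0 + 0.5 * x + rng.normal(0, 0.1, 100))
        spec = fit_model(pd.DataFrame({"x": x}), y, transform="ln")
        grid = pd.DataFrame({"x": np.linspace(-2, 2, 50)})
        preds = predict_cells(spec, grid)
        assert (np.diff(preds) >= 0).all()


class TestSampleEfficiency:
    def test_paper_ba_row(self):
        assert round(100 * sample_efficiency(0.635), 1) == 40.6

    def test_paper_tpa_row(self):
        assert round(100 * sample_efficiency(0.568), 1) == 49.3

    def test_perfect_correlation(self):
        assert sample_efficiency(1.0) == 0.0

    def test_no_correlation(self):
        assert sample_efficiency(0.0) == 2.0

    @pytest.mark.parametrize("bad", [-0.1, 1.1, 2.0])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            sample_efficiency(bad)


class TestNormalityTest:
    def test_normal_sample_not_rejected_usually(self):
        rejections = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            _, p = pearson_normality_test(rng.normal(size=300))
            rejections += p < 0.05
        assert rejections <= 8

    def test_uniform_sample_rejected(self, rng):
        _, p = pearson_normality_test(rng.uniform(-1, 1, size=2000))
        assert p < 0.01
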