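import numpy as np
import pytest
from scipy import integrate, stats

import scnormlm as sc
from scnormlm.normalization import (
    CellVarianceModel,
    CovariateTerm,
    intercept_term,
    orthonormalize_rows,
    summary_base_covariates,
)


def _quadrature_mean_log(g: int, n: int) -> float:
    """Independent oracle: E[ln p] under Beta(1+g, 1+n-g) by quadrature."""
    a, b = 1.0 + g, 1.0 + n - g
    f = lambda p: np.log(p) * stats.beta.pdf(p, a, b)
    mode = a / (a + b)
    val, _ = integrate.quad(f, 0, 1, points=[min(mode, 0.999)], limit=200)
    return val


class TestBayesianLogExpression:
    def test_known_values(self):
        m = sc.CountMatrix(np.array([[0], [0]]), ["g1", "g2"], ["c1"])
        Y = sc.bayesian_log_expression(m)  # n = 0 for the single cell
        assert Y == pytest.approx(np.full((2, 1), -1.0))  # psi(1) - psi(2)

        m = sc.CountMatrix(np.array([[9], [0]]), ["g1", "g2"], ["c1"])
        Y = sc.bayesian_log_expression(m)  # n = 9
        assert Y[0, 0] == pytest.approx(-0.1, abs=1e-12)  # psi(10) - psi(11)

    def test_deep_zero_cell(self):
        m = sc.CountMatrix(np.array([[0], [9998]]), ["g1", "g2"], ["c1"])
        Y = sc.bayesian_log_expression(m)
        assert Y[0, 0] == pytest.approx(-9.787506, abs=1e-5)

    @pytest.mark.parametrize("g", [0, 1, 5, 20, 50])
    @pytest.mark.parametrize("n_extra", [0, 1, 10, 1000, 9950])
    def test_matches_beta_posterior_quadrature(self, g, n_extra):
        n = g + n_extra
        m = sc.CountMatrix(np.array([[g], [n - g]]), ["a", "b"], ["c"])
        assert sc.bayesian_log_expression(m)[0, 0] == pytest.approx(
            _quadrature_mean_log(g, n), abs=1e-8
        )

    def test_all_entries_negative(self, null_dataset):
        assert (sc.bayesian_log_expression(null_dataset.counts) < 0).all()


class TestSummaryCovariates:
    def test_base_values(self):
        m = sc.CountMatrix(np.array([[3], [0], [5]]), list("abc"), ["c1"])
        cov = sc.summary_covariates(m)
        labels = [t.label for t in cov.terms]
        assert labels == ["intercept", "log_reads", "log_reads_sq", "n_zero_genes"]
        assert cov.values[1, 0] == pytest.approx(np.log(8))
        assert cov.values[2, 0] == pytest.approx(np.log(8) ** 2)
        assert cov.values[3, 0] == 1.0

    def test_product_term(self):
        m = sc.CountMatrix(np.array([[3], [0], [5]]), list("abc"), ["c1"])
        cov = sc.summary_covariates(m, [intercept_term(), CovariateTerm("b1*b2", order=(1, 1))])
        assert cov.values[1, 0] == pytest.approx(np.log(8) * 1.0)

    def test_identical_cells_constant_rows(self):
        m = sc.CountMatrix(np.tile([[2], [0]], (1, 4)), ["a", "b"], list("wxyz"))
        bases = summary_base_covariates(m)
        assert (np.ptp(bases, axis=1) == 0).all()

    def test_zero_total_cell_rejected(self):
        m = sc.CountMatrix(np.array([[0], [0]]), ["a", "b"], ["c1"])
        with pytest.raises(ValueError, match="zero total"):
            sc.summary_covariates(m)


class TestAggregateCovariates:
    def test_orthonormal_postconditions(self, null_dataset):
        m = null_dataset.counts
        cov = sc.aggregate_covariates(None, sc.summary_covariates(m))
        assert cov.orthonormalized
        body = cov.values[1:]  # non-intercept rows
        assert np.allclose(body.mean(axis=1), 0, atol=1e-10)
        gram = body @ body.T
        assert np.allclose(gram, np.eye(len(body)), atol=1e-8)

    def test_duplicate_row_dropped(self, null_dataset):
        m = null_dataset.counts
        summary = sc.summary_covariates(m)
        dup = summary.with_rows(summary.values[1:2], [CovariateTerm("dup_b1", order=(1, 0))])
        with pytest.warns(UserWarning, match="collinear"):
            cov = sc.aggregate_covariates(None, dup)
        assert cov.n_terms == 4  # intercept + b1 + b1^2 + b2, duplicate gone

    def test_span_preserved(self, null_dataset):
        m = null_dataset.counts
        raw = sc.summary_covariates(m)
        ortho = sc.aggregate_covariates(None, raw)
        rng = np.random.default_rng(0)
        v = rng.normal(size=m.n_cells)
        for C in (raw.values, ortho.values):
            coef, *_ = np.linalg.lstsq(C.T, v, rcond=None)
            proj = coef @ C
            v = v  # same target
            if C is raw.values:
                p_raw = proj
            else:
                assert np.allclose(proj, p_raw, atol=1e-8)

    def test_categorical_one_hot_all_levels(self):
        import pandas as pd

        cells = list("stuvwxyz")
        m = sc.CountMatrix(np.arange(1, 25).reshape(3, 8), list("abc"), cells)
        tab = sc.CovariateTable(
            pd.DataFrame({"batch": ["p", "q"] * 4, "ok": np.arange(8.0)}, index=cells),
            {"batch": "categorical", "ok": "continuous"},
        )
        with pytest.warns(UserWarning, match="collinear"):
            cov = sc.aggregate_covariates(tab, sc.summary_covariates(m))
        assert cov.raw_categorical.shape == (2, 8)  # both levels retained raw
        assert set(cov.raw_categorical.ravel()) == {0.0, 1.0}

    def test_more_covariates_than_cells_rejected(self):
        m = sc.CountMatrix(np.array([[1, 2], [3, 4]]), ["a", "b"], ["c1", "c2"])
        with pytest.raises(ValueError, match="more covariates"):
            sc.aggregate_covariates(None, sc.summary_covariates(m))


class TestCellVariance:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(5, 40))
        C = sc.CovariateSet(np.ones((1, 40)), [intercept_term()], orthonormalized=True)
        model = sc.estimate_cell_variance(Y, C)
        assert np.allclose(model.alpha_y[:, 0], Y.mean(axis=1))
        v_expect = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=0)
        assert np.allclose(model.v, v_expect)
        geo = np.exp(np.mean(np.log(v_expect)))
        assert np.allclose(model.v_hat, geo)

    def test_scale_homogeneity(self, null_dataset):
        m, _ = sc.qc_filter(null_dataset.counts)
        Y = sc.bayesian_log_expression(m)
        C = sc.aggregate_covariates(None, sc.summary_covariates(m))
        base = sc.estimate_cell_variance(Y, C)
        scaled = sc.estimate_cell_variance(3.0 * Y, C)
        assert np.allclose(scaled.v, 9.0 * base.v)
        assert np.allclose(scaled.v_hat, 9.0 * base.v_hat)

    def test_single_noisy_gene_drives_variance(self):
        rng = np.random.default_rng(5)
        C = sc.CovariateSet(np.ones((1, 50)), [intercept_term()], orthonormalized=True)
        Y = np.vstack([np.full(50, 2.0), np.full(50, -1.0), rng.normal(0, 1, 50)])
        model = sc.estimate_cell_variance(Y, C)
        resid = Y[2] - Y[2].mean()
        assert np.allclose(model.v, resid**2, atol=1e-12)

    def test_degenerate_variance_rejected(self):
        C = sc.CovariateSet(np.ones((1, 10)), [intercept_term()], orthonormalized=True)
        with pytest.raises(ValueError, match="degenerate"):
            sc.estimate_cell_variance(np.ones((3, 10)), C)


class TestNormalize:
    def _setup(self, null_dataset):
        m, _ = sc.qc_filter(null_dataset.counts)
        Y = sc.bayesian_log_expression(m)
        C = sc.aggregate_covariates(None, sc.summary_covariates(m))
        model = sc.estimate_cell_variance(Y, C)
        return m, Y, C, model

    def test_unit_variance_is_identity(self, null_dataset):
        m, Y, C, model = self._setup(null_dataset)
        model.v_hat = np.ones(m.n_cells)
        expr = sc.normalize(Y, C, model, m)
        assert np.allclose(expr.y_tilde, Y)

    def test_fully_expressed_gene_untouched(self, null_dataset):
        m, Y, C, model = self._setup(null_dataset)
        expr = sc.normalize(Y, C, model, m)
        full = m.zeros_per_gene == 0
        assert full.any()
        assert np.allclose(expr.y_tilde[full], Y[full])
        assert (expr.gamma[full] == 0).all()

    def test_max_zero_gene_fully_scaled(self, null_dataset):
        m, Y, C, model = self._setup(null_dataset)
        expr = sc.normalize(Y, C, model, m)
        i = int(np.argmax(m.zeros_per_gene))
        assert expr.gamma[i] == 1.0
        v_rel = model.v_hat / np.exp(np.mean(np.log(model.v_hat)))
        fitted = (model.alpha_y @ C.values)[i]
        expect = fitted + (Y[i] - fitted) / np.sqrt(v_rel)
        assert np.allclose(expr.y_tilde[i], expect)

    def test_gamma_range_and_normalizer(self, null_dataset):
        m, Y, C, model = self._setup(null_dataset)
        expr = sc.normalize(Y, C, model, m)
        assert expr.gamma.min() >= 0 and expr.gamma.max() == 1.0
        gtil = m.zeros_per_gene
        assert np.allclose(expr.gamma, gtil / gtil.max())

    def test_no_zeros_anywhere_noop(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(1, 50, size=(6, 30))
        m = sc.CountMatrix(counts, [f"g{i}" for i in range(6)], [f"c{j}" for j in range(30)])
        Y = sc.bayesian_log_expression(m)
        C = sc.aggregate_covariates(None, sc.summary_covariates(m))
        model = sc.estimate_cell_variance(Y, C)
        expr = sc.normalize(Y, C, model, m)
        assert (expr.gamma == 0).all()
        assert np.allclose(expr.y_tilde, Y)

    def test_covariate_scaling_exempts_categorical(self, null_dataset):
        import pandas as pd

        m, _ = sc.qc_filter(null_dataset.counts)
        tab = sc.CovariateTable(
            pd.DataFrame({"b": ["u" if j % 2 else "w" for j in range(m.n_cells)]}, index=m.cell_ids),
            {"b": "categorical"},
        )
        with pytest.warns(UserWarning, match="collinear"):
            expr = sc.normalize_counts(m, existing=tab)
        cat_rows = expr.covariates_tilde.values[[t.is_categorical for t in expr.covariates_tilde.terms]]
        assert set(np.unique(cat_rows)) == {0.0, 1.0}  # raw one-hot, unscaled


class TestRemoveOutliers:
    def _model(self, v_hat):
        v_hat = np.asarray(v_hat, float)
        return CellVarianceModel(
            alpha_y=np.zeros((1, 1)), v=v_hat.copy(), alpha_v=np.zeros(1), v_hat=v_hat
        )

    def test_identical_cells_no_outliers(self):
        keep = sc.remove_outliers(self._model(np.full(100, 2.0)))
        assert keep.all()

    def test_single_gross_outlier_flagged(self):
        rng = np.random.default_rng(0)
        inv = np.concatenate([rng.normal(1.0, 0.01, 999), [0.1]])
        keep = sc.remove_outliers(self._model(1.0 / inv))
        assert not keep[-1]
        assert keep[:-1].all()

    def test_zero_threshold_keeps_everything(self):
        rng = np.random.default_rng(1)
        inv = np.concatenate([rng.normal(1.0, 0.01, 99), [50.0]])
        cfg = sc.OutlierConfig(bonferroni_p_threshold=0.0)
        assert sc.remove_outliers(self._model(1.0 / inv), cfg).all()

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            sc.remove_outliers(self._model(np.array([1.0, 2.0])))


class TestFittedMeanPreservation:
    def test_regression_recovers_fitted_values(self):
        # With constant v_hat the rescaling is per-gene affine, so refitting
        # the normalized rows on the covariates must return the same fitted
        # values as the raw fit, for both untouched and fully-scaled genes.
        rng = np.random.default_rng(9)
        counts = rng.poisson(2.0, size=(8, 60))
        counts[:, 0] += 1
        m = sc.CountMatrix(counts, [f"g{i}" for i in range(8)], [f"c{j}" for j in range(60)])
        Y = sc.bayesian_log_expression(m)
        C = sc.aggregate_covariates(None, sc.summary_covariates(m))
        model = sc.estimate_cell_variance(Y, C)
        model.v_hat = np.full(m.n_cells, 4.0)
        expr = sc.normalize(Y, C, model, m)
        fitted = model.alpha_y @ C.values
        coef, *_ = np.linalg.lstsq(C.values.T, expr.y_tilde.T, rcond=None)
        refit = coef.T @ C.values
        for i in np.flatnonzero((expr.gamma == 0) | (expr.gamma == 1)):
            assert np.allclose(refit[i], fitted[i], atol=1e-8)
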