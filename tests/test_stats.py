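"""Rank correlations, parallel analysis, PCA and trend summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transientpop import parallel_analysis, pca, spearman_rho, summarise_trends
from transientpop.errors import ValidationError
from transientpop.stats import correlation_matrix, drop_nonfinite


class TestSpearman:
    def test_perfect_agreement(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)

    def test_perfect_reversal(self):
        assert spearman_rho([1, 2, 3], [30, 20, 10]).rho == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_oracle(self):
        """Six points with one tie: Pearson correlation of explicit
        mid-ranks is the expected value."""
        x = [1.0, 2.0, 2.0, 4.0, 5.0, 6.0]
        y = [3.0, 1.0, 4.0, 2.0, 6.0, 5.0]
        rank_x = [1.0, 2.5, 2.5, 4.0, 5.0, 6.0]
        rank_y = [3.0, 1.0, 4.0, 2.0, 6.0, 5.0]
        expected = np.corrcoef(rank_x, rank_y)[0, 1]
        assert spearman_rho(x, y).rho == pytest.approx(expected, rel=1e-12)

    def test_constant_input_flagged(self):
        with pytest.raises(ValidationError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_reports_p_value_and_n(self):
        res = spearman_rho(np.arange(20.0), np.arange(20.0) ** 2)
        assert res.n == 20
        assert res.p_value < 0.05
        assert res.rounded() == 1.0

    @given(
        shift=st.floats(min_value=-5, max_value=5),
        power=st.integers(min_value=1, max_value=3),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, shift, power):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        base = spearman_rho(x, y).rho
        transformed = spearman_rho(x, (y + shift) ** (2 * power - 1)).rho
        assert transformed == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestParallelAnalysis:
    def test_pure_noise_retains_zero(self):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((500, 9))
        result = parallel_analysis(data, n_iter=1000, seed=5)
        assert result.n_retained == 0

    def test_planted_factor_retains_one(self):
        rng = np.random.default_rng(12)
        n = 500
        factor = rng.standard_normal(n)
        data = rng.standard_normal((n, 9))
        for j in range(4):
            data[:, j] = 0.9 * factor + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        result = parallel_analysis(data, n_iter=1000, seed=5)
        assert result.n_retained == 1

    def test_correlated_pair_orders_eigenvalues(self):
        rng = np.random.default_rng(13)
        n = 300
        base = rng.standard_normal(n)
        data = rng.standard_normal((n, 5))
        data[:, 0] = base
        data[:, 1] = base
        result = parallel_analysis(data, n_iter=200, seed=1)
        assert result.adjusted_eigenvalues[0] > result.adjusted_eigenvalues[1]

    def test_retention_non_increasing_in_quantile(self):
        rng = np.random.default_rng(14)
        n = 300
        factor = rng.standard_normal(n)
        data = rng.standard_normal((n, 6))
        for j in range(3):
            data[:, j] += 0.7 * factor
        kept = [
            parallel_analysis(data, n_iter=300, quantile=q, seed=2).n_retained
            for q in (0.05, 0.5, 0.95, 0.999)
        ]
        assert kept == sorted(kept, reverse=True)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(15)
        data = rng.standard_normal((200, 4))
        a = parallel_analysis(data, n_iter=150, seed=9)
        b = parallel_analysis(data, n_iter=150, seed=9)
        np.testing.assert_array_equal(a.bias, b.bias)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            parallel_analysis(np.ones((5, 9)), seed=0)


def _frame(array, prefix="v"):
    return pd.DataFrame(
        array, columns=[f"{prefix}{j}" for j in range(array.shape[1])]
    )


class TestPca:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal(50)
        frame = _frame(np.column_stack([x, 3 * x + 1]))
        result = pca(frame, frame.columns, n_retained=1)
        assert result.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_isotropic_data_near_uniform_fractions(self):
        rng = np.random.default_rng(22)
        frame = _frame(rng.standard_normal((4000, 4)))
        result = pca(frame, frame.columns, n_retained=1)
        assert np.all(np.abs(result.explained_variance_fraction - 0.25) < 0.05)

    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(23)
        X = rng.standard_normal((20, 4)) @ rng.standard_normal((4, 4))
        frame = _frame(X)
        result = pca(frame, frame.columns, n_retained=4)
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        values, vectors = np.linalg.eigh(np.corrcoef(Z, rowvar=False))
        values = values[::-1]
        np.testing.assert_allclose(
            result.explained_variance_fraction, values / values.sum(), atol=1e-9
        )
        # loadings agree up to sign
        for k in range(4):
            v = vectors[:, ::-1][:, k]
            got = result.loadings[:, k]
            assert min(
                np.abs(got - v).max(), np.abs(got + v).max()
            ) == pytest.approx(0.0, abs=1e-9)

    def test_fractions_sum_to_one_and_orthonormal(self):
        rng = np.random.default_rng(24)
        frame = _frame(rng.standard_normal((60, 5)))
        result = pca(frame, frame.columns, n_retained=2)
        assert result.explained_variance_fraction.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(
            result.loadings.T @ result.loadings, np.eye(5), atol=1e-9
        )

    def test_zero_variance_column_named(self):
        frame = _frame(np.ones((10, 2)))
        frame["v1"] = np.arange(10.0)
        with pytest.raises(ValidationError, match="v0"):
            pca(frame, frame.columns)

    def test_loading_report_orders_by_importance(self):
        rng = np.random.default_rng(25)
        x = rng.standard_normal(100)
        frame = _frame(
            np.column_stack([x, x + 0.1 * rng.standard_normal(100),
                             rng.standard_normal(100)])
        )
        result = pca(frame, frame.columns, n_retained=1)
        report = result.loading_report()
        assert report[0][0].startswith(("v0", "v1"))


class TestTrendsAndPlumbing:
    def test_single_year_matches_raw_statistics(self):
        frame = pd.DataFrame(
            {"country": ["A"] * 5, "year": [2000] * 5,
             "lambda1": [0.9, 1.0, 1.1, 1.2, 0.8]}
        )
        out = summarise_trends(frame, metrics=["lambda1"])
        row = out.iloc[0]
        assert row["mean"] == pytest.approx(1.0)
        assert row["median"] == pytest.approx(1.0)
        assert row["q025"] == pytest.approx(np.quantile(frame["lambda1"], 0.025))

    def test_constant_metric_collapses_quantiles(self):
        frame = pd.DataFrame(
            {"country": ["A"] * 4, "year": [2000, 2000, 2001, 2001],
             "lambda1": [1.0] * 4}
        )
        out = summarise_trends(frame, metrics=["lambda1"])
        assert (out["q025"] == out["q975"]).all()

    def test_threshold_year_detected(self):
        frame = pd.DataFrame(
            {
                "country": ["A"] * 6,
                "year": [1970, 1971, 1972, 1973, 1974, 1975],
                "lambda1": [1.05, 1.02, 1.01, 1.001, 0.99, 0.97],
            }
        )
        out = summarise_trends(frame, metrics=["lambda1"])
        assert out.attrs["lambda1_below_1_year"] == 1974

    def test_drop_nonfinite_counts(self):
        frame = pd.DataFrame(
            {"a": [1.0, np.nan, 2.0, np.inf], "b": [1.0, 2.0, 3.0, 4.0]}
        )
        clean, dropped = drop_nonfinite(frame, ["a", "b"])
        assert dropped == 2
        assert len(clean) == 2

    def test_correlation_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(31)
        frame = _frame(rng.standard_normal((40, 4)))
        corr = correlation_matrix(frame, frame.columns)
        np.testing.assert_allclose(corr.values, corr.values.T)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)
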