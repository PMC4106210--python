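import numpy as np
import pandas as pd
import pytest

import nlgxe as n
from nlgxe import (
    CellMeansTable,
    DegenerateIndexError,
    Family,
    NonPositiveResponseError,
    ResponseParams,
    compute_environment_index,
    evaluate_response,
)

from conftest import records_from_matrix


class TestEnvironmentIndex:
    @pytest.mark.parametrize(
        "means,expected",
        [
            ([[1, 3], [2, 4]], [1.5, 3.5]),
            ([[5, 7]], [5, 7]),
            ([[0, 2], [1, 3], [2, 4]], [1, 3]),
        ],
    )
    def test_index_is_column_mean(self, means, expected):
        table = CellMeansTable.from_means(means)
        assert table.env_index == pytest.approx(expected)

    def test_from_records_averages_blocks(self):
        rec = records_from_matrix(np.array([[1.0, 3, 5], [2, 4, 6]]))
        rec2 = rec.copy()
        rec2["block"] = "B2"
        rec2["value"] += 1.0
        table = compute_environment_index(pd.concat([rec, rec2]))
        assert table.n_reps == 2
        assert table.means[0] == pytest.approx([1.5, 3.5, 5.5])
        assert table.env_index == pytest.approx([2, 4, 6])

    def test_too_few_environments_rejected(self):
        rec = records_from_matrix(np.array([[1.0, 2], [3, 4]]))
        with pytest.raises(DegenerateIndexError):
            compute_environment_index(rec)

    def test_multi_year_records_rejected(self):
        a = records_from_matrix(np.ones((2, 3)), year="y1")
        b = records_from_matrix(np.ones((2, 3)), year="y2")
        with pytest.raises(ValueError, match="year"):
            compute_environment_index(pd.concat([a, b]))

    def test_all_missing_genotype_dropped_with_warning(self, caplog):
        means = np.array([[1.0, 2, 3], [np.nan] * 3, [3, 4, 5]])
        table = CellMeansTable.from_means(means, genotypes=["A", "B", "C"])
        with caplog.at_level("WARNING", logger="nlgxe"):
            out = compute_environment_index(table)
        assert out.genotypes == ["A", "C"]
        assert "B" in caplog.text


class TestClosedFormFits:
    def test_linear_exact(self, make_table):
        t = make_table([1, 2, 3], [2, 4, 6])
        f = n.fit_linear(t, "G01")
        assert f.params.a == pytest.approx(0, abs=1e-12)
        assert f.params.b == pytest.approx(2)
        assert f.rss == pytest.approx(0, abs=1e-20)

    def test_linear_needs_three_environments(self, make_table):
        t = make_table([0, 3], [0, 2])
        with pytest.raises(ValueError, match=">= 3"):
            n.fit_linear(t, "G01")

    def test_linear_matches_normal_equations(self, make_table):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 10)
        y = rng.normal(size=10)
        f = n.fit_linear(make_table(x, y), "G01")
        X = np.column_stack([np.ones(10), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert f.params.free_values == pytest.approx(beta, abs=1e-10)
        assert f.rss == pytest.approx(float(np.sum((y - X @ beta) ** 2)), abs=1e-10)

    def test_linear_slope_invariant_to_intercept_shift(self, make_table):
        rng = np.random.default_rng(2)
        x = np.linspace(1, 8, 8)
        y = 1 + 0.8 * x + rng.normal(0, 0.1, 8)
        f1 = n.fit_linear(make_table(x, y), "G01")
        f2 = n.fit_linear(make_table(x, y + 5.0), "G01")
        assert f2.params.b == pytest.approx(f1.params.b, abs=1e-10)
        assert f2.params.a == pytest.approx(f1.params.a + 5.0, abs=1e-9)

    def test_parabola_exact_and_constant(self, make_table):
        x = np.array([0.0, 1, 2, 3])
        f = n.fit_parabola(make_table(x, x ** 2), "G01")
        assert f.params.free_values == pytest.approx([0, 0, 1], abs=1e-10)
        assert f.rss == pytest.approx(0, abs=1e-18)
        f2 = n.fit_parabola(make_table(x, np.full(4, 5.0)), "G01")
        assert f2.params.free_values == pytest.approx([5, 0, 0], abs=1e-10)

    def test_parabola_matches_polynomial_oracle(self, make_table):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 5, 12)
        y = rng.normal(size=12)
        f = n.fit_parabola(make_table(x, y), "G01")
        oracle = np.polyfit(x, y, 2)[::-1]
        assert f.params.free_values == pytest.approx(oracle, abs=1e-9)

    def test_recip_quad_exact(self, make_table):
        x = np.array([0.0, 1, 2, 3])
        f = n.fit_reciprocal_quadratic(make_table(x, 1 / (1 + x)), "G01")
        assert f.params.free_values == pytest.approx([1, 1, 0], abs=1e-10)
        assert f.rss == pytest.approx(0, abs=1e-18)

    def test_recip_quad_rejects_nonpositive(self, make_table):
        t = make_table([0, 1, 2, 3], [1.0, 0.0, 2.0, 3.0])
        with pytest.raises(NonPositiveResponseError, match="G01"):
            n.fit_reciprocal_quadratic(t, "G01")

    def test_recip_quad_transform_scale_oracle(self, make_table):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 4, 10)
        y = 1.0 / (1.0 + 0.5 * x + 0.1 * x ** 2) + rng.uniform(0.01, 0.05, 10)
        f = n.fit_reciprocal_quadratic(make_table(x, y), "G01")
        oracle = np.polyfit(x, 1.0 / y, 2)[::-1]
        assert f.params.free_values == pytest.approx(oracle, abs=1e-9)


class TestNonlinearFits:
    def test_cauchy_noise_free_recovery(self, make_table):
        x = np.linspace(10, 90, 15)
        truth = ResponseParams("cauchy", k=10, x_max=50, r=20)
        f = n.fit_cauchy(make_table(x, evaluate_response(truth, x)), "G01")
        assert f.converged
        assert f.params.free_values == pytest.approx([10, 50, 20], abs=1e-6)
        assert f.rss == pytest.approx(0, abs=1e-12)

    def test_cauchy_constant_response_is_degenerate(self, make_table):
        f = n.fit_cauchy(make_table([1, 2, 3, 4], [2.0, 2, 2, 2]), "G01")
        assert not f.converged

    def test_cauchy_consistency_under_small_noise(self, make_table):
        rng = np.random.default_rng(5)
        x = np.linspace(10, 90, 40)
        truth = ResponseParams("cauchy", k=10, x_max=50, r=20)
        mu = evaluate_response(truth, x)
        errs = []
        for rep in range(30):
            y = mu + rng.normal(0, 0.01, x.size)
            f = n.fit_cauchy(make_table(x, y), "G01", seed=rep)
            errs.append(np.abs(f.params.free_values - [10, 50, 20]))
        med = np.median(errs, axis=0)
        assert np.all(med < [0.02, 0.1, 0.2])

    def test_logistic_noise_free_recovery(self, make_table):
        x = np.arange(0, 7, 1.0)
        y = 1.0 / (2.0 + 3.0 * 0.5 ** x)
        f = n.fit_logistic(make_table(x, y), "G01")
        assert f.converged
        assert f.params.free_values == pytest.approx([2, 3, 0.5], abs=1e-6)

    def test_logistic_decreasing_response_unconverged(self, make_table):
        x = np.arange(0, 6, 1.0)
        f = n.fit_logistic(make_table(x, 5.0 - 0.5 * x), "G01")
        assert not f.converged

    def test_logistic_constant_response_is_flat(self, make_table):
        x = np.arange(0, 6, 1.0)
        f = n.fit_logistic(make_table(x, np.full(6, 0.25)), "G01")
        assert f.params.a == pytest.approx(4.0, rel=1e-6)
        assert f.params.b == pytest.approx(0.0, abs=1e-8)
        pred = f.predict(x)
        assert np.ptp(pred) == pytest.approx(0, abs=1e-6)

    def test_normal_noise_free_recovery(self, make_table):
        x = np.linspace(0, 6, 11)
        truth = ResponseParams("normal", k=np.sqrt(2 * np.pi), x_max=3, r=1)
        f = n.fit_normal(make_table(x, evaluate_response(truth, x)), "G01")
        assert f.converged
        assert f.params.free_values == pytest.approx(
            [np.sqrt(2 * np.pi), 3, 1], abs=1e-6
        )

    def test_normal_rejects_zero_response(self, make_table):
        t = make_table([0, 1, 2, 3], [1.0, 2.0, 0.0, 1.0])
        with pytest.raises(NonPositiveResponseError):
            n.fit_normal(t, "G01")

    def test_normal_symmetric_data_centers_optimum(self, make_table):
        x = np.array([0.0, 1, 2, 3, 4, 5, 6])
        y = np.exp(-0.5 * (x - 3) ** 2)  # symmetric about x = 3
        f = n.fit_normal(make_table(x, y), "G01")
        assert f.params.x_max == pytest.approx(3.0, abs=1e-8)

    def test_refinement_never_worse_than_initializer(self, make_table):
        rng = np.random.default_rng(6)
        x = np.linspace(2, 8, 12)
        truth = ResponseParams("cauchy", k=6, x_max=5, r=2)
        for rep in range(5):
            y = evaluate_response(truth, x) + rng.normal(0, 0.2, x.size)
            f = n.fit_cauchy(make_table(x, np.abs(y) + 0.1), "G01", seed=rep)
            if f.rss_init is not None:
                assert f.rss <= f.rss_init + 1e-12


class TestSweep:
    def test_all_fittable_no_skips(self, small_met):
        table = compute_environment_index(small_met.records)
        sweep = n.fit_all_genotypes(table, "linear")
        assert len(sweep.fits) == 8
        assert sweep.skipped == {}

    def test_sparse_genotype_lands_in_skip_list(self):
        means = np.full((3, 5), np.nan)
        means[0] = [1, 2, 3, 4, 5.0]
        means[1] = [2, 3, 4, 5, 6.0]
        means[2, :2] = [1.0, 2.0]  # only 2 environments
        table = CellMeansTable.from_means(means, genotypes=["A", "B", "C"])
        sweep = n.fit_all_genotypes(table, "linear")
        assert {f.genotype for f in sweep.fits} == {"A", "B"}
        assert "C" in sweep.skipped

    def test_sweep_deterministic_given_seed(self, small_met):
        table = compute_environment_index(small_met.records)
        s1 = n.fit_all_genotypes(table, "cauchy", seed=9)
        s2 = n.fit_all_genotypes(table, "cauchy", seed=9)
        for f1, f2 in zip(s1.fits, s2.fits):
            assert np.array_equal(f1.params.free_values, f2.params.free_values)
            assert f1.rss == f2.rss
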