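import numpy as np
import pandas as pd
import pytest

import nlgxe as n
from nlgxe import (
    CellMeansTable,
    Family,
    GenotypeFit,
    ResponseParams,
    StabilityClass,
    UnbalancedDataError,
    anova_partition,
    classify_stability,
    compute_environment_index,
    partition_gxe,
    percent_table,
)

from conftest import records_from_matrix


def brute_force_anova(values):
    """Explicit mean-decomposition oracle; values has shape (G, E, r)."""
    G, E, r = values.shape
    grand = values.mean()
    gm = values.mean(axis=(1, 2))
    em = values.mean(axis=(0, 2))
    cm = values.mean(axis=2)
    ss_G = sum(E * r * (gm[i] - grand) ** 2 for i in range(G))
    ss_E = sum(G * r * (em[j] - grand) ** 2 for j in range(E))
    ss_GxE = sum(
        r * (cm[i, j] - gm[i] - em[j] + grand) ** 2
        for i in range(G) for j in range(E)
    )
    ss_err = sum(
        (values[i, j, k] - cm[i, j]) ** 2
        for i in range(G) for j in range(E) for k in range(r)
    )
    ss_tot = ((values - grand) ** 2).sum()
    return ss_tot, ss_G, ss_E, ss_GxE, ss_err


def records_from_cube(values, year="y1"):
    G, E, r = values.shape
    rows = []
    for i in range(G):
        for j in range(E):
            for k in range(r):
                rows.append(
                    {"year": year, "environment": f"E{j+1}", "block": f"B{k+1}",
                     "genotype": f"G{i+1}", "value": values[i, j, k]}
                )
    return pd.DataFrame(rows)


class TestAnova:
    def test_worked_2x2_interaction(self):
        rec = records_from_matrix(np.array([[0.0, 2], [0, 4]]))
        an = anova_partition(rec)
        assert an.ss_GxE == pytest.approx(1.0)
        assert an.n_reps == 1

    def test_additive_table_has_zero_interaction(self):
        g = np.array([1.0, 2, 5])
        e = np.array([0.0, 3, 4, 7])
        rec = records_from_matrix(g[:, None] + e[None, :])
        an = anova_partition(rec)
        assert an.ss_GxE == pytest.approx(0, abs=1e-12)

    def test_matches_brute_force_on_random_layout(self):
        rng = np.random.default_rng(7)
        values = rng.normal(5, 2, size=(4, 6, 3))
        an = anova_partition(records_from_cube(values))
        ss_tot, ss_G, ss_E, ss_GxE, ss_err = brute_force_anova(values)
        assert an.ss_total == pytest.approx(ss_tot, rel=1e-9)
        assert an.ss_G == pytest.approx(ss_G, rel=1e-9)
        assert an.ss_E == pytest.approx(ss_E, rel=1e-9)
        assert an.ss_GxE == pytest.approx(ss_GxE, rel=1e-9)
        assert an.ss_error == pytest.approx(ss_err, rel=1e-9)
        assert (an.df_G, an.df_E, an.df_GxE, an.df_error) == (3, 5, 15, 4 * 6 * 2)

    def test_incomplete_genotype_excluded(self, caplog):
        rec = records_from_matrix(np.arange(12.0).reshape(3, 4))
        rec = rec[~((rec.genotype == "G3") & (rec.environment == "E1"))]
        with caplog.at_level("WARNING", logger="nlgxe"):
            an = anova_partition(rec)
        assert "G3" in caplog.text
        assert an.df_G == 1  # two genotypes remain

    def test_unequal_replication_is_error(self):
        rec = records_from_cube(np.random.default_rng(0).normal(size=(2, 3, 2)))
        rec = rec.drop(rec.index[-1])  # one plot missing from one cell
        with pytest.raises(UnbalancedDataError):
            anova_partition(rec)


def _linear_fit_through_points(genotype, x, y):
    b, a = np.polyfit(x, y, 1)
    resid = y - (a + b * x)
    return GenotypeFit(
        genotype, ResponseParams("linear", a=a, b=b),
        float(resid @ resid), len(x), True, 2,
    )


class TestGxEPartition:
    def test_worked_2x2_linear_closed_form(self):
        """Two genotypes, two environments: the whole interaction is slope
        heterogeneity, so the linear curves explain 100% of it."""
        means = np.array([[0.0, 2], [0, 4]])
        rec = records_from_matrix(means)
        an = anova_partition(rec)
        table = CellMeansTable.from_means(means)
        x = table.env_index
        fits = [
            _linear_fit_through_points(g, x, means[i])
            for i, g in enumerate(table.genotypes)
        ]
        part = partition_gxe(table, fits, an)
        assert part.ss_residual == pytest.approx(0, abs=1e-12)
        assert part.pct_explained == pytest.approx(100.0)
        # heterogeneity-of-regressions closed form
        b = [f.params.b for f in fits]
        sxx = np.sum((x - x.mean()) ** 2)
        assert sum((bi - 1) ** 2 for bi in b) * sxx == pytest.approx(an.ss_GxE)

    def test_exact_fits_explain_everything(self, small_met):
        # heterogeneous linear truth, vanishing noise: fits reproduce cells
        sim = n.simulate_met(
            n.MetSimConfig(n_genotypes=6, n_environments=8, n_blocks=1,
                           family="linear", noise_sd=0.0, seed=3)
        )
        an = anova_partition(sim.records)
        table = compute_environment_index(sim.records)
        sweep = n.fit_all_genotypes(table, "linear")
        part = partition_gxe(table, sweep, an)
        assert part.pct_explained == pytest.approx(100.0, abs=1e-6)

    def test_additive_fits_explain_nothing(self):
        rng = np.random.default_rng(8)
        means = rng.normal(5, 1, size=(4, 5))
        rec = records_from_matrix(means)
        an = anova_partition(rec)
        table = CellMeansTable.from_means(means)
        x = table.env_index
        fits = [
            GenotypeFit(
                g,
                ResponseParams("linear", a=means[i].mean() - x.mean(), b=1.0),
                0.0, 5, True, 2,
            )
            for i, g in enumerate(table.genotypes)
        ]
        part = partition_gxe(table, fits, an)
        assert part.ss_explained == pytest.approx(0, abs=1e-10 * an.ss_GxE)
        assert part.pct_explained == pytest.approx(0, abs=1e-8)

    def test_decomposition_identity_and_heterogeneity_oracle(self):
        rng = np.random.default_rng(9)
        means = rng.normal(5, 1, size=(5, 7))
        rec = records_from_matrix(means)
        an = anova_partition(rec)
        table = CellMeansTable.from_means(means)
        sweep = n.fit_all_genotypes(table, "linear")
        part = partition_gxe(table, sweep, an)
        assert part.ss_explained + part.ss_residual == pytest.approx(
            an.ss_GxE, rel=1e-10
        )
        x = table.env_index
        sxx = float(np.sum((x - x.mean()) ** 2))
        het = sum((f.params.b - 1) ** 2 for f in sweep.fits) * sxx
        assert part.ss_explained == pytest.approx(het, rel=1e-8)

    def test_mean_linear_slope_is_one(self):
        rng = np.random.default_rng(10)
        means = rng.normal(5, 1, size=(6, 9))
        table = CellMeansTable.from_means(means)
        sweep = n.fit_all_genotypes(table, "linear")
        assert np.mean([f.params.b for f in sweep.fits]) == pytest.approx(
            1.0, abs=1e-10
        )

    @pytest.mark.parametrize("family", ["linear", "parabola", "cauchy"])
    def test_pct_invariant_to_unit_changes(self, family):
        """Positive rescaling never changes the explained share (every
        family is closed under y -> s*y); additive shifts are checked for
        the polynomial families, which are closed under y -> y + c."""
        sim = n.simulate_met(
            n.MetSimConfig(n_genotypes=6, n_environments=10, n_blocks=2,
                           family="cauchy", noise_sd=0.2, seed=12)
        )

        def pct(records):
            an = anova_partition(records)
            table = compute_environment_index(records)
            sweep = n.fit_all_genotypes(table, family, seed=0)
            return partition_gxe(table, sweep, an).pct_explained

        base = pct(sim.records)
        scaled = sim.records.assign(value=sim.records.value * 3.0)
        assert pct(scaled) == pytest.approx(base, abs=1e-3)
        if family in ("linear", "parabola"):
            shifted = sim.records.assign(value=sim.records.value + 7.0)
            assert pct(shifted) == pytest.approx(base, abs=1e-6)


class TestStability:
    def _table(self, n_env=12):
        x = np.linspace(0, 11, n_env)
        means = np.vstack([x, 2 * x - x])  # index equals x
        return CellMeansTable.from_means(means), x

    def _fit(self, genotype, b, se, x, n_obs):
        sxx = float(np.sum((x - x.mean()) ** 2))
        dev_ms = se ** 2 * sxx
        rss = dev_ms * (n_obs - 2)
        return GenotypeFit(
            genotype, ResponseParams("linear", a=0.0, b=b), rss, n_obs, True, 2
        )

    def test_significantly_steep_slope_is_low_stability(self):
        table, x = self._table()
        fits = [self._fit("G01", 1.6, 0.1, x, 12), self._fit("G02", 1.0, 0.1, x, 12)]
        reports = classify_stability(fits, table)
        assert reports[0].fw_class is StabilityClass.LOW_STABILITY
        assert reports[0].t_stat == pytest.approx(6.0)

    def test_insignificant_slope_deviation_is_average(self):
        table, x = self._table()
        fits = [self._fit("G01", 1.2, 0.5, x, 12), self._fit("G02", 1.0, 0.5, x, 12)]
        reports = classify_stability(fits, table)
        assert reports[0].fw_class is StabilityClass.AVERAGE

    def test_exact_unit_slope_is_average_and_er_candidate(self):
        x = np.linspace(0, 11, 12)
        rng = np.random.default_rng(13)
        w = rng.normal(0, 0.05, 12)
        # G01 lies exactly on y = x + 1; the wiggles of G02/G03 cancel in
        # the column means, so the index remains x
        means = np.vstack([x + 1.0, x - 1.0 + w, x - w])
        table = CellMeansTable.from_means(means)
        assert table.env_index == pytest.approx(x)
        sweep = n.fit_all_genotypes(table, "linear")
        reports = classify_stability(sweep, table)
        rep = {r.genotype: r for r in reports}
        assert all(r.fw_class is StabilityClass.AVERAGE for r in reports)
        assert rep["G01"].er_stable           # perfect fit, high mean yield
        assert not rep["G02"].er_stable       # below-median mean yield
        assert rep["G01"].dev_ms == pytest.approx(0, abs=1e-18)

    def test_few_environments_get_null_dev_ms(self, caplog):
        x = np.linspace(0, 2, 3)
        table = CellMeansTable.from_means(np.vstack([x, x]))
        fits = [
            GenotypeFit("G01", ResponseParams("linear", a=0, b=1), 0.0, 3, True, 2),
            GenotypeFit("G02", ResponseParams("linear", a=0, b=1), 0.0, 3, True, 2),
        ]
        with caplog.at_level("WARNING", logger="nlgxe"):
            reports = classify_stability(fits, table)
        assert reports[0].dev_ms is None


class TestPercentTable:
    def test_multi_year_adds_average_row(self):
        recs = []
        for year, seed in (("1995", 21), ("1996", 22)):
            sim = n.simulate_met(
                n.MetSimConfig(n_genotypes=5, n_environments=8, n_blocks=2,
                               family="linear", noise_sd=0.2, seed=seed, year=year)
            )
            recs.append(sim.records)
        out = percent_table(pd.concat(recs), ["linear", "parabola"], seed=0)
        assert set(out["year"]) == {"1995", "1996", "average"}
        avg = out[out.year == "average"].set_index("family")["pct_explained"]
        per = out[out.year != "average"]
        for fam in ("linear", "parabola"):
            assert avg[fam] == pytest.approx(
                per[per.family == fam]["pct_explained"].mean()
            )

    def test_pct_bounded(self):
        sim = n.simulate_met(
            n.MetSimConfig(n_genotypes=6, n_environments=8, n_blocks=2,
                           family="cauchy", noise_sd=0.3, seed=5)
        )
        out = percent_table(sim.records, ["linear", "cauchy"], seed=0)
        assert ((out["pct_explained"] >= 0) & (out["pct_explained"] <= 100)).all()
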