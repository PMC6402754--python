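import numpy as np
import pandas as pd
import pytest
from scipy import stats

from specyield.indices import builtin_definitions, index_table
from specyield.regression import (
    GROUPING_SCHEMES,
    iter_groups,
    production_function,
    significance_stars,
    simple_linear_fit,
    subset_regressions,
)


class TestSimpleLinearFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = simple_linear_fit(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 0.3 * x + rng.normal(size=40)
        res = simple_linear_fit(x, y)
        assert res.r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_independent_noise_rarely_correlates(self):
        """R^2 < 0.02 in at least 95 of 100 seeded null runs at n=1000."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = simple_linear_fit(rng.normal(size=1000), rng.normal(size=1000))
            hits += res.r2 < 0.02
        assert hits >= 95

    def test_critical_r_at_alpha_05_df8(self):
        """At n=10 the two-sided 5% point sits near |r| = 0.632 (R^2 = 0.40)."""
        # independent closed-form check: t = r sqrt(df/(1-r^2)), df = 8
        def p_of_r(r, n=10):
            t = r * np.sqrt((n - 2) / (1 - r**2))
            return 2 * stats.t.sf(abs(t), n - 2)

        r_crit = np.sqrt(0.40)
        assert p_of_r(0.632) == pytest.approx(0.05, abs=0.001)
        # construct data with an exact sample correlation r
        x = np.arange(10.0)
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        e = np.zeros(10)
        e[0], e[-1] = 1.0, 1.0
        e = e - e.mean()
        e -= (e @ xc) * xc
        e /= np.linalg.norm(e)
        for r in (r_crit, 0.60):
            res = simple_linear_fit(x, r * xc + np.sqrt(1 - r**2) * e)
            assert res.p == pytest.approx(p_of_r(r), abs=1e-10)
        assert simple_linear_fit(x, r_crit * xc + np.sqrt(1 - r_crit**2) * e).p < 0.05
        assert simple_linear_fit(x, 0.60 * xc + np.sqrt(1 - 0.36) * e).p > 0.05

    def test_constant_x_flagged_undefined(self):
        res = simple_linear_fit(np.ones(5), np.arange(5.0))
        assert not res.defined
        assert np.isnan(res.slope)

    def test_star_thresholds_consistent(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.051) == ""


class TestGroupingSchemes:
    def test_reference_design_sample_counts(self, small_experiment):
        """Scheme group sizes are {10, 6, 6, 10, 30} on the 2x3x5x3 design."""
        _, dataset, agronomy, _ = small_experiment
        table = index_table(dataset, builtin_definitions()[:1])
        merged = table.join(agronomy.set_index("sample_id"), how="inner")
        expected = {
            "per_irrigation": {10},
            "per_density": {6},
            "pooled_rates_means": {6},
            "pooled_density_means": {10},
            "all_pooled": {30},
        }
        for scheme, sizes in expected.items():
            got = {
                len(grp)
                for _, grp in iter_groups(
                    merged.reset_index(), scheme, [table.columns[0], "GY"]
                )
            }
            assert got == sizes, scheme

    def test_group_counts_per_scheme(self, small_experiment):
        _, dataset, agronomy, _ = small_experiment
        table = index_table(dataset, builtin_definitions()[:1])
        merged = table.join(agronomy.set_index("sample_id"), how="inner")
        n_groups = {
            s: sum(
                1 for _ in iter_groups(merged.reset_index(), s, [table.columns[0], "GY"])
            )
            for s in GROUPING_SCHEMES
        }
        assert n_groups == {
            "per_irrigation": 3,
            "per_density": 5,
            "pooled_rates_means": 1,
            "pooled_density_means": 1,
            "all_pooled": 1,
        }

    def test_means_taken_over_index_values_not_spectra(self, small_experiment):
        """Pooled schemes average derived index values (indices are nonlinear
        in reflectance, so averaging spectra first would give different
        numbers)."""
        _, dataset, agronomy, _ = small_experiment
        table = index_table(dataset, builtin_definitions())
        merged = table.join(agronomy.set_index("sample_id"), how="inner").reset_index()
        ((_, pooled),) = iter_groups(
            merged, "pooled_rates_means", ["MSI", "GY"]
        )
        # manual mean of per-plot MSI for season 1, full irrigation
        mask = (merged.season == 1) & (merged.irrigation == 1.0)
        expected = merged.loc[mask, "MSI"].mean()
        row = pooled[(pooled.season == 1) & (pooled.irrigation == 1.0)]
        assert row["MSI"].iloc[0] == pytest.approx(expected, rel=1e-12)


class TestSubsetRegressions:
    def test_planted_linear_link_recovered(self, small_experiment):
        """A trait built as a linear function of one index regresses to
        R^2 ~ 1 under all_pooled."""
        _, dataset, agronomy, _ = small_experiment
        table = index_table(dataset, builtin_definitions())
        agro = agronomy.copy().set_index("sample_id")
        agro["FAKE"] = 3.0 * table["NDVI"] + 5.0
        out = subset_regressions(
            table, agro.reset_index(), "all_pooled", traits=("FAKE",)
        )
        cell = out[(out["index"] == "NDVI")].iloc[0]
        assert cell.r2 >= 0.95
        assert cell.n == 30

    def test_tidy_output_columns_and_stars(self, small_experiment):
        _, dataset, agronomy, _ = small_experiment
        table = index_table(dataset, builtin_definitions()[:3])
        out = subset_regressions(table, agronomy, "per_irrigation", traits=("GY",))
        assert set(out.columns) >= {
            "scheme", "group", "index", "trait", "n", "slope",
            "intercept", "r2", "p", "stars", "significant",
        }
        assert (out.n == 10).all()
        # starred iff p below level
        for _, row in out.iterrows():
            assert row.significant == (row.p <= 0.05)

    def test_misaligned_keys_rejected(self, small_experiment):
        _, dataset, agronomy, _ = small_experiment
        table = index_table(dataset, builtin_definitions()[:1])
        with pytest.raises(ValueError, match="align"):
            subset_regressions(table, agronomy.iloc[:10], "all_pooled")


class TestProductionFunction:
    def test_exact_construction(self):
        et = np.linspace(100, 600, 12)
        gy = 1.5 * (et - 80.0)
        res, basal = production_function(gy, et)
        assert res.slope == pytest.approx(1.5)
        assert basal == pytest.approx(80.0)

    def test_zero_intercept(self):
        et = np.linspace(100, 600, 8)
        res, basal = production_function(2.0 * et, et)
        assert basal == pytest.approx(0.0, abs=1e-9)

    def test_negative_slope_flagged(self):
        et = np.linspace(100, 600, 8)
        res, basal = production_function(-1.0 * et + 900, et)
        assert basal is None

    def test_basal_et_recovery_over_seeds(self, coarse_grid):
        """The basal ET of the noisy generator stays within 10% of the
        noise-free reference over repeated simulations."""
        from specyield.synthetic import SyntheticConfig, generate_experiment

        ref_cfg = SyntheticConfig(grid=coarse_grid, seed=0, seasons=1)
        rows = [
            (ref_cfg.mean_gy(1, r, d), ref_cfg.seasonal_et_mean(1, r))
            for r in ref_cfg.irrigation_rates
            for d in ref_cfg.densities
        ]
        _, ref_basal = production_function(*zip(*rows))
        basals = []
        for seed in range(50):
            cfg = SyntheticConfig(grid=coarse_grid, seed=seed, seasons=1)
            _, agro, _ = generate_experiment(cfg)
            _, basal = production_function(agro["GY"], agro["ET"])
            basals.append(basal)
        assert np.mean(basals) == pytest.approx(ref_basal, rel=0.10)
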