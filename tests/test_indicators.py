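"""Indicator-OTU scan: deltas, regressions, Bonferroni control, recovery."""

import numpy as np
import pytest
from scipy import stats

import marshtransplant as mt
from marshtransplant.io import ValidationError
from marshtransplant.indicators import _vectorized_ols
from marshtransplant.simulate import scan_calibration_config


class TestEnvDelta:
    def test_wb_to_ab_temperature_delta(self, site_lookup):
        # ln(24.2) - ln(17.1) evaluates to 0.3473 (direct evaluation of the formula)
        dv = mt.env_delta("WB", "AB", "air_temp", site_lookup)
        assert dv == pytest.approx(np.log(24.2) - np.log(17.1), abs=1e-12)
        assert dv == pytest.approx(0.3473, abs=5e-5)

    def test_antisymmetry_for_directional_variables(self, site_lookup):
        for var in ("air_temp", "pct_nitrogen", "salinity"):
            fwd = mt.env_delta("PI", "RC", var, site_lookup)
            assert mt.env_delta("RC", "PI", var, site_lookup) == pytest.approx(-fwd)

    def test_same_site_delta_is_zero(self, site_lookup):
        for var in mt.SCAN_VARIABLES:
            assert mt.env_delta("WB", "WB", var, site_lookup) == 0.0

    def test_geodist_conventions(self, site_lookup):
        d = mt.haversine_km(41.580, -70.521, 41.625, -71.324)
        assert mt.env_delta("WB", "PI", "geographic_distance", site_lookup) == \
            pytest.approx(np.log1p(d))
        assert mt.env_delta("WB", "PI", "geographic_distance", site_lookup,
                            convention="raw_symmetric") == pytest.approx(d)
        # symmetric either way
        assert mt.env_delta("PI", "WB", "geographic_distance", site_lookup) == \
            pytest.approx(np.log1p(d))


class TestRegressionDataset:
    def make_dataset(self, sites):
        design = mt.build_design(sites, 3, 3, (("PI", "JR", 2), ("WB", "AB", 3)))
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(3, len(design)))  # all-prevalent OTUs
        table = mt.OTUTable(["oA", "oB", "oC"], [d.sample_id for d in design], counts)
        return table, design

    def test_share_point_for_worked_example(self, sites, site_lookup):
        table, design = self.make_dataset(sites)
        i = table.otu_index("oA")
        table.counts[i, :] = 10
        j = table.sample_ids.index("WBtoAB_1")
        table.counts[i, j] = 100
        # grand total: 87*10 + 100 = 970 -> adjust to make 1000 for a clean 10%
        table.counts[i, table.sample_ids.index("WBtoAB_2")] = 40
        ds = mt.assemble_regression_dataset(table, design, sites, "oA", "air_temp")
        k = ds.sample_ids.index("WBtoAB_1")
        assert ds.y[k] == pytest.approx(0.10)
        assert ds.x[k] == pytest.approx(np.log(24.2) - np.log(17.1))

    def test_controls_contribute_x_zero(self, sites):
        table, design = self.make_dataset(sites)
        ds = mt.assemble_regression_dataset(table, design, sites, "oB", "air_temp")
        for m in design:
            if m.sample_class != "transplant":
                assert ds.x[ds.sample_ids.index(m.sample_id)] == 0.0

    def test_point_per_included_sample(self, sites):
        table, design = self.make_dataset(sites)
        ds = mt.assemble_regression_dataset(table, design, sites, "oC", "salinity")
        assert len(ds.x) == len(ds.y) == 88
        assert ds.y.sum() == pytest.approx(1.0)  # shares over all samples

    def test_low_prevalence_otu_skipped_not_raised(self, sites, caplog):
        table, design = self.make_dataset(sites)
        table.counts[0, :50] = 0
        with caplog.at_level("INFO"):
            ds = mt.assemble_regression_dataset(table, design, sites, "oA", "air_temp")
        assert ds is None
        assert any("prevalence" in r.message for r in caplog.records)


class TestLinearRegression:
    def test_exact_fit(self):
        x = np.arange(5.0)
        fit = mt.linear_regression_test(x, 2 * x + 1)
        assert (fit.slope, fit.intercept, fit.r_squared) == (2.0, 1.0, 1.0)
        assert fit.p_value == 0.0 and fit.degenerate

    def test_constant_response(self):
        fit = mt.linear_regression_test(np.arange(6.0), np.full(6, 3.0))
        assert fit.slope == 0.0 and fit.r_squared == 0.0 and fit.p_value == 1.0

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        y = 0.7 * x + rng.normal(size=10)
        fit = mt.linear_regression_test(x, y)
        X = np.column_stack([x, np.ones(10)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / 8
        se = np.sqrt(s2 / ((x - x.mean()) @ (x - x.mean())))
        t = beta[0] / se
        p = 2 * stats.t.sf(abs(t), 8)
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert fit.slope == pytest.approx(beta[0], abs=1e-10)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)
        assert fit.p_value == pytest.approx(p, abs=1e-10)

    def test_vectorized_ols_matches_linregress(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        Y = rng.normal(size=(5, 30))
        slope, intercept, r2, p = _vectorized_ols(x, Y)
        for i in range(5):
            f = stats.linregress(x, Y[i])
            assert slope[i] == pytest.approx(f.slope, abs=1e-12)
            assert intercept[i] == pytest.approx(f.intercept, abs=1e-12)
            assert r2[i] == pytest.approx(f.rvalue ** 2, abs=1e-12)
            assert p[i] == pytest.approx(f.pvalue, abs=1e-12)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            mt.linear_regression_test(np.ones(5), np.arange(5.0))


class TestBonferroni:
    def test_published_correction_two_significant_figures(self):
        thr = mt.bonferroni_threshold(0.001, 63_337 * 4)
        assert f"{thr:.1e}" == "3.9e-09"

    @pytest.mark.parametrize("alpha,n,expected", [(0.05, 1, 0.05), (0.001, 4, 0.00025)])
    def test_simple_arithmetic(self, alpha, n, expected):
        assert mt.bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_monotone_decreasing_in_tests(self):
        thrs = [mt.bonferroni_threshold(0.01, n) for n in (1, 10, 100, 1000)]
        assert thrs == sorted(thrs, reverse=True)


class TestRunScan:
    def test_single_strong_indicator_is_top_hit(self):
        cfg = scan_calibration_config(
            seed=13, indicators=(mt.IndicatorSpec(5, "air_temp", -2.0,
                                                  base_abundance=0.01),))
        table, metadata, sites, truth = mt.simulate_experiment(cfg)
        summary = mt.run_scan(table, metadata, sites)
        top = summary.results[0]
        assert (top.otu_id, top.variable) == ("OTU0005", "air_temp")
        assert top.passes

    def test_reversing_directions_negates_slopes_only(self, sites):
        cfg = scan_calibration_config(seed=14)
        table, metadata, _, _ = mt.simulate_experiment(cfg)
        reversed_meta = [
            mt.SampleMetadata(m.sample_id, m.destination_site, m.origin_site,
                              m.sample_class, m.replicate)
            for m in metadata
        ]
        fwd = mt.run_scan(table, metadata, sites,
                          mt.ScanConfig(variables=("air_temp", "pct_nitrogen", "salinity")))
        rev = mt.run_scan(table, reversed_meta, sites,
                          mt.ScanConfig(variables=("air_temp", "pct_nitrogen", "salinity")))
        f = {(r.otu_id, r.variable): r for r in fwd.results}
        for r in rev.results:
            assert r.slope == pytest.approx(-f[(r.otu_id, r.variable)].slope, abs=1e-12)
            assert r.r_squared == pytest.approx(f[(r.otu_id, r.variable)].r_squared, abs=1e-12)
            assert r.p_value == pytest.approx(f[(r.otu_id, r.variable)].p_value, abs=1e-12)

    def test_pass_set_monotone_in_alpha(self):
        cfg = scan_calibration_config(seed=15)
        table, metadata, sites, _ = mt.simulate_experiment(cfg)
        small = mt.run_scan(table, metadata, sites, mt.ScanConfig(alpha=0.0001))
        large = mt.run_scan(table, metadata, sites, mt.ScanConfig(alpha=0.01))
        assert set(small.passing) <= set(large.passing)

    def test_naive_test_count_reproduces_published_arithmetic(self):
        cfg = scan_calibration_config(seed=16, n_otus=20)
        table, metadata, sites, _ = mt.simulate_experiment(cfg)
        summary = mt.run_scan(table, metadata, sites)
        assert summary.n_tests_naive == 20 * 4
        # the published scan: 63,337 OTUs x 4 variables
        assert 63_337 * len(mt.SCAN_VARIABLES) == 253_348

    def test_no_survivor_returns_empty_with_warning(self, sites, caplog):
        design = mt.build_design(sites, 1, 1)
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 2, size=(5, len(design)))  # sparse: none prevalent
        counts[:, 0] += 1
        table = mt.OTUTable([f"o{i}" for i in range(5)],
                            [d.sample_id for d in design], counts)
        with caplog.at_level("WARNING"):
            summary = mt.run_scan(table, design, sites)
        assert summary.results == [] and summary.n_passes == 0
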