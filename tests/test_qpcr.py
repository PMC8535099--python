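import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gutferm as gf
from gutferm.qpcr import aggregate_replicates, cycle_to_log10_gcn

from _oracles import ols_normal_equations


class TestFitStandardCurve:
    def test_exact_line_through_two_points(self):
        curve = gf.fit_standard_curve([(6.0, 20.0), (3.0, 30.0)])
        assert curve.slope == pytest.approx(-10.0 / 3.0)
        assert curve.intercept == pytest.approx(40.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_perfect_dilution_series_has_unit_efficiency(self):
        # slope -3.3219 cycles/decade <=> exact doubling per cycle
        pts = [(x, 40.0 - 3.3219 * x) for x in (2, 3, 4, 5, 6)]
        curve = gf.fit_standard_curve(pts)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-4)
        assert curve.efficiency_ok()

    def test_matches_normal_equation_oracle(self, rng):
        x = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        y = 38.0 - 3.4 * x + rng.normal(0, 0.3, 5)
        curve = gf.fit_standard_curve(zip(x, y))
        slope, intercept = ols_normal_equations(x, y)
        assert curve.slope == pytest.approx(slope, abs=1e-9)
        assert curve.intercept == pytest.approx(intercept, abs=1e-9)

    @given(st.permutations(range(5)), st.floats(0.5, 3.0))
    def test_point_order_and_cycle_scaling(self, perm, scale):
        x = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([33.4, 30.1, 26.6, 23.5, 20.0])
        base = gf.fit_standard_curve(zip(x, y))
        shuffled = gf.fit_standard_curve([(x[i], y[i]) for i in perm])
        assert shuffled.slope == pytest.approx(base.slope)
        scaled = gf.fit_standard_curve(zip(x, y * scale))
        assert scaled.slope == pytest.approx(base.slope * scale)
        assert scaled.intercept == pytest.approx(base.intercept * scale)

    def test_degenerate_inputs(self):
        with pytest.raises(gf.DegenerateCurveError):
            gf.fit_standard_curve([(3.0, 20.0), (3.0, 25.0)])
        with pytest.raises(gf.DegenerateCurveError):
            gf.fit_standard_curve([(3.0, 20.0)])


class TestCycleInversion:
    CURVE = gf.StandardCurve(slope=-3.3219, intercept=40.0, r_squared=1.0)

    def test_cycle_at_intercept_gives_scale_only(self):
        value, ok = cycle_to_log10_gcn(40.0, self.CURVE, volume_scale=100.0)
        assert value == pytest.approx(np.log10(100.0))
        assert ok

    def test_hand_computed_inversion(self):
        value, _ = cycle_to_log10_gcn(20.0, self.CURVE)
        assert value == pytest.approx((20.0 - 40.0) / -3.3219, abs=1e-9)
        assert value == pytest.approx(6.02, abs=0.01)

    @given(st.floats(0.5, 11.5))
    def test_forward_inverse_identity(self, log10_copies):
        cycle = self.CURVE.intercept + self.CURVE.slope * log10_copies
        value, ok = cycle_to_log10_gcn(cycle, self.CURVE)
        assert value == pytest.approx(log10_copies, abs=1e-9)
        assert ok

    def test_out_of_range_flagged_not_raised(self):
        value, ok = cycle_to_log10_gcn(45.0, self.CURVE)  # below 1 copy
        assert value < 0 and not ok


class TestQuantify:
    def test_cq_table_to_abundances(self):
        curve = gf.StandardCurve(slope=-3.3219, intercept=40.0, r_squared=1.0)
        cq = pd.DataFrame([
            dict(taxon="Eubacteria", treatment="FOS", time_h=6.0,
                 experiment=1, replicate=r, cq=13.5 + 0.1 * r)
            for r in (1, 2, 3)])
        table = gf.quantify(cq, {"Eubacteria": curve})
        assert len(table.data) == 3
        expected = (13.6 - 40.0) / -3.3219
        assert table.data["log10_gcn"].iloc[0] == pytest.approx(expected)
        assert not table.data["out_of_range"].any()

    def test_missing_curve_is_error(self):
        cq = pd.DataFrame([dict(taxon="E. coli", treatment="FOS", time_h=6.0,
                                experiment=1, replicate=1, cq=30.0)])
        with pytest.raises(gf.ValidationError, match="E. coli"):
            gf.quantify(cq, {})


class TestAggregateReplicates:
    def test_mean_and_sample_sd(self):
        rows = [dict(taxon="Eubacteria", treatment="FOS", time_h=6.0,
                     experiment=1, replicate=r + 1, log10_gcn=v)
                for r, v in enumerate([8.2, 8.3, 8.4])]
        table = gf.TaxonAbundanceTable(pd.DataFrame(rows))
        agg = aggregate_replicates(table)
        assert agg["mean"].iloc[0] == pytest.approx(8.3)
        assert agg["sd"].iloc[0] == pytest.approx(0.1)
        assert agg["n"].iloc[0] == 3

    def test_constant_replicates_sd_zero(self):
        rows = [dict(taxon="Eubacteria", treatment="FOS", time_h=6.0,
                     experiment=1, replicate=r, log10_gcn=8.0)
                for r in (1, 2, 3)]
        agg = aggregate_replicates(gf.TaxonAbundanceTable(pd.DataFrame(rows)))
        assert agg["sd"].iloc[0] == 0.0

    def test_single_replicate_sd_missing_not_zero(self):
        rows = [dict(taxon="Eubacteria", treatment="FOS", time_h=6.0,
                     experiment=1, replicate=1, log10_gcn=8.0)]
        agg = aggregate_replicates(gf.TaxonAbundanceTable(pd.DataFrame(rows)))
        assert np.isnan(agg["sd"].iloc[0])

    def test_matches_brute_force_on_simulated_replicates(self, rng):
        vals = rng.normal(8.0, 0.2, 6)
        rows = [dict(taxon="Eubacteria", treatment="FOS", time_h=6.0,
                     experiment=1 + r // 3, replicate=1 + r % 3,
                     log10_gcn=v) for r, v in enumerate(vals)]
        agg = aggregate_replicates(gf.TaxonAbundanceTable(pd.DataFrame(rows)))
        mean = sum(vals) / 6
        sd = (sum((v - mean) ** 2 for v in vals) / 5) ** 0.5
        assert agg["mean"].iloc[0] == pytest.approx(mean, abs=1e-12)
        assert agg["sd"].iloc[0] == pytest.approx(sd, abs=1e-12)

    def test_technical_level_groups_by_experiment(self, sim_slow):
        taxa, _, _ = sim_slow
        tech = aggregate_replicates(taxa, level="technical")
        pooled = aggregate_replicates(taxa, level="all")
        assert "experiment" in tech.columns
        assert len(tech) == 2 * len(pooled)
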