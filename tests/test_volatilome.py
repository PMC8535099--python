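import numpy as np
import pandas as pd
import pytest

import gutferm as gf
from conftest import make_voc_table
from gutferm.volatilome import to_case_matrix


class TestAnovaScreen:
    def test_constant_compound_not_significant(self):
        vocs = make_voc_table({
            "flat": {("FOS", 0.0): [5, 5, 5], ("FOS", 24.0): [5, 5, 5]},
            "moves": {("FOS", 0.0): [1, 1.1, 0.9], ("FOS", 24.0): [9, 9.1, 8.9]},
        })
        out = gf.anova_screen(vocs).set_index("compound")
        assert out.loc["flat", "p"] == 1.0
        assert not out.loc["flat", "significant"]
        assert bool(out.loc["flat", "constant"])
        assert out.loc["moves", "significant"]

    def test_exclusion_list(self):
        vocs = make_voc_table({
            "a": {("FOS", 0.0): [1, 2], ("FOS", 24.0): [9, 10]},
            "b": {("FOS", 0.0): [1, 2], ("FOS", 24.0): [9, 10]},
        })
        out = gf.anova_screen(vocs, exclude=["b"])
        assert list(out["compound"]) == ["a"]

    def test_fdr_adjustment_monotone(self):
        vocs = make_voc_table({
            c: {("FOS", 0.0): [1, 2], ("FOS", 24.0): [v, v + 1]}
            for c, v in [("strong", 50), ("weak", 3), ("none", 1)]})
        raw = gf.anova_screen(vocs)
        adj = gf.anova_screen(vocs, fdr=True)
        merged = raw.merge(adj, on="compound", suffixes=("_raw", "_fdr"))
        assert (merged["p_adjusted_fdr"] >= merged["p_raw"] - 1e-15).all()


class TestMeanCenter:
    def test_simple_values(self):
        vocs = make_voc_table({"x": {("FOS", 0.0): [1.0, 2.0, 3.0]}})
        centered, means = gf.mean_center(vocs)
        assert sorted(centered.data["value"]) == [-1.0, 0.0, 1.0]
        assert means["x"] == 2.0
        assert centered.unit == "centered"

    def test_column_sums_vanish(self, sim_slow):
        _, vocs, _ = sim_slow
        centered, _ = gf.mean_center(vocs)
        sums = centered.data.groupby("compound")["value"].sum()
        assert np.allclose(sums, 0.0, atol=1e-9)

    def test_round_trip_with_stored_means(self, sim_slow):
        _, vocs, _ = sim_slow
        centered, means = gf.mean_center(vocs)
        back = centered.data["value"] + centered.data["compound"].map(means)
        orig = vocs.data["value"].where(vocs.data["detected"], 0.0)
        np.testing.assert_allclose(back, orig, atol=1e-12)


class TestBaselineShift:
    def test_condition_equal_to_baseline_has_zero_delta(self):
        vocs = make_voc_table({"x": {("BL", 0.0): [2.0, 2.0],
                                     ("FOS", 24.0): [2.0, 2.0]}})
        centered, _ = gf.mean_center(vocs)
        shifts = gf.baseline_shift(centered, letters=False).data
        assert (shifts["delta"] == 0).all()

    def test_baseline_rows_always_zero(self, sim_slow):
        _, vocs, _ = sim_slow
        centered, _ = gf.mean_center(vocs)
        shifts = gf.baseline_shift(centered, letters=False).data
        assert (shifts.loc[shifts["time_h"] == 0.0, "delta"] == 0).all()

    def test_matches_spreadsheet_oracle(self):
        table = {"a": {("BL", 0.0): [1.0, 3.0], ("FOS", 24.0): [5.0, 7.0]},
                 "b": {("BL", 0.0): [10.0, 10.0], ("FOS", 24.0): [7.0, 9.0]},
                 "c": {("BL", 0.0): [0.0, 0.0], ("FOS", 24.0): [4.0, 4.0]}}
        vocs = make_voc_table(table)
        centered, _ = gf.mean_center(vocs)
        shifts = gf.baseline_shift(centered, letters=False).data
        got = shifts.set_index(["compound", "treatment"])["delta"]
        # deltas survive centering: condition mean - baseline mean
        assert got[("a", "FOS")] == pytest.approx(6.0 - 2.0, abs=1e-12)
        assert got[("b", "FOS")] == pytest.approx(8.0 - 10.0, abs=1e-12)
        assert got[("c", "FOS")] == pytest.approx(4.0, abs=1e-12)

    def test_missing_baseline_is_error(self):
        vocs = make_voc_table({"x": {("FOS", 24.0): [1.0, 2.0]}})
        with pytest.raises(gf.ValidationError, match="baseline"):
            gf.baseline_shift(vocs)

    def test_letters_flag_significant_shift(self):
        vocs = make_voc_table({"x": {("BL", 0.0): [1, 1.1, 0.9, 1.0],
                                     ("FOS", 24.0): [9, 9.1, 8.9, 9.0]}})
        centered, _ = gf.mean_center(vocs)
        shifts = gf.baseline_shift(centered).data.set_index("treatment")
        assert shifts.loc["BL", "letter"] != shifts.loc["FOS", "letter"]


class TestClassPercentChange:
    CLASSES = gf.VocClassMap({"a1": "SCFA", "a2": "SCFA", "b": "BCFA"})

    def test_unchanged_compounds_give_zero(self):
        vocs = make_voc_table({c: {("BL", 0.0): [4.0, 4.0],
                                   ("FOS", 24.0): [4.0, 4.0]}
                               for c in ("a1", "a2", "b")})
        out = gf.class_percent_change(vocs, self.CLASSES, "FOS", 24.0)
        assert np.allclose(out["percent_change"], 0.0, atol=1e-12)

    def test_single_class_arithmetic(self):
        vocs = make_voc_table({"a1": {("BL", 0.0): [10.0, 10.0],
                                      ("FOS", 24.0): [13.7, 13.7]}})
        cmap = gf.VocClassMap({"a1": "SCFA"})
        out = gf.class_percent_change(vocs, cmap, "FOS", 24.0)
        assert out["percent_change"].iloc[0] == pytest.approx(37.0, abs=1e-9)

    def test_multi_class_matches_brute_force(self):
        vocs = make_voc_table({
            "a1": {("BL", 0.0): [2.0, 4.0], ("FOS", 24.0): [5.0, 7.0]},
            "a2": {("BL", 0.0): [1.0, 1.0], ("FOS", 24.0): [0.5, 0.5]},
            "b": {("BL", 0.0): [8.0, 8.0], ("FOS", 24.0): [2.0, 2.0]}})
        out = gf.class_percent_change(vocs, self.CLASSES, "FOS", 24.0)
        got = out.set_index("voc_class")["percent_change"]
        assert got["SCFA"] == pytest.approx(100 * (6.5 - 4.0) / 4.0, abs=1e-12)
        assert got["BCFA"] == pytest.approx(100 * (2.0 - 8.0) / 8.0, abs=1e-12)

    def test_split_invariance(self):
        """Splitting a compound into two that sum to it leaves sums alone."""
        whole = make_voc_table({"a1": {("BL", 0.0): [6.0, 6.0],
                                       ("FOS", 24.0): [9.0, 9.0]}})
        split = make_voc_table({"a1": {("BL", 0.0): [2.0, 2.0],
                                       ("FOS", 24.0): [3.0, 3.0]},
                                "a2": {("BL", 0.0): [4.0, 4.0],
                                       ("FOS", 24.0): [6.0, 6.0]}})
        one = gf.class_percent_change(whole, gf.VocClassMap({"a1": "SCFA"}),
                                      "FOS", 24.0)
        two = gf.class_percent_change(
            split, gf.VocClassMap({"a1": "SCFA", "a2": "SCFA"}), "FOS", 24.0)
        assert one["percent_change"].iloc[0] == pytest.approx(
            two["percent_change"].iloc[0], abs=1e-12)

    def test_newly_detected_class(self):
        vocs = make_voc_table({"a1": {("BL", 0.0): [0.0, 0.0],
                                      ("FOS", 24.0): [3.0, 3.0]}})
        out = gf.class_percent_change(vocs, gf.VocClassMap({"a1": "SCFA"}),
                                      "FOS", 24.0)
        assert out["newly_detected"].iloc[0]
        assert np.isnan(out["percent_change"].iloc[0])

    def test_centered_units_rejected(self, sim_slow):
        _, vocs, _ = sim_slow
        centered, _ = gf.mean_center(vocs)
        with pytest.raises(gf.ValidationError):
            gf.class_percent_change(centered, self.CLASSES, "FOS", 24.0)


class TestPercentShift:
    def test_hand_arithmetic(self):
        vocs = make_voc_table({"x": {("BL", 0.0): [4.0, 4.0],
                                     ("FOS", 24.0): [5.0, 5.0]}})
        res = gf.percent_shift(vocs, "x", ("BL", 0.0), ("FOS", 24.0))
        assert res.percent == pytest.approx(25.0, abs=1e-12)
        assert not res.newly_detected

    def test_equal_means_zero(self):
        vocs = make_voc_table({"x": {("BL", 0.0): [4.0, 6.0],
                                     ("FOS", 24.0): [5.0, 5.0]}})
        assert gf.percent_shift(vocs, "x", ("BL", 0.0),
                                ("FOS", 24.0)).percent == 0.0

    def test_newly_detected_instead_of_percent(self):
        vocs = make_voc_table({"x": {("BL", 0.0): [0.0, 0.0],
                                     ("FOS", 24.0): [5.0, 5.0]}})
        res = gf.percent_shift(vocs, "x", ("BL", 0.0), ("FOS", 24.0))
        assert res.newly_detected and np.isnan(res.percent)

    def test_toy_series_oracle(self):
        vocs = make_voc_table({"x": {("BL", 0.0): [3.0, 5.0],
                                     ("FLS", 24.0): [5.5, 6.5]}})
        res = gf.percent_shift(vocs, "x", ("BL", 0.0), ("FLS", 24.0))
        assert res.percent == pytest.approx(100 * (6.0 - 4.0) / 4.0, abs=1e-12)


class TestOrdination:
    def test_collinear_data_one_component(self, rng):
        t = rng.normal(size=20)
        data = pd.DataFrame({"a": t, "b": 2 * t, "c": -t})
        ord_ = gf.ordination_scores(data, n_components=2)
        assert ord_.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_reconstruction(self, rng):
        data = pd.DataFrame(rng.normal(size=(10, 4)))
        ord_ = gf.ordination_scores(data, n_components=4)
        recon = ord_.scores.to_numpy() @ ord_.loadings.to_numpy().T
        centered = data - data.mean(axis=0)
        np.testing.assert_allclose(recon, centered, atol=1e-9)

    def test_isotropic_gaussian_near_equal_variance(self, rng):
        data = pd.DataFrame(rng.normal(size=(4000, 2)))
        ord_ = gf.ordination_scores(data, n_components=2)
        assert ord_.explained_variance_ratio[0] == pytest.approx(0.5, abs=0.05)
        assert ord_.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_rank_truncation_warns(self, rng):
        t = rng.normal(size=8)
        data = pd.DataFrame({"a": t, "b": 2 * t})
        with pytest.warns(UserWarning, match="rank"):
            ord_ = gf.ordination_scores(data, n_components=2)
        assert ord_.scores.shape[1] == 1

    def test_sign_convention(self, sim_slow):
        _, vocs, _ = sim_slow
        centered, _ = gf.mean_center(vocs)
        ord_ = gf.ordination_scores(to_case_matrix(centered).fillna(0.0))
        for col in ord_.loadings.columns:
            top = ord_.loadings[col].abs().idxmax()
            assert ord_.loadings.loc[top, col] > 0
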