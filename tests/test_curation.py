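"""Frost/drought database curation rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frostdrought import curation


def frost_row(species="Abies alba", organ="branch", method="EL",
              value=-25.0, date="2015-01-15", lat=45.0, rate=2.0,
              age="adult"):
    return {"species": species, "organ": organ, "method": method,
            "value_C": value, "date": date, "lat": lat,
            "rate_C_per_h": rate, "age_class": age}


class TestMidwinter:
    def test_january_north_kept_april_dropped(self):
        df = pd.DataFrame([frost_row(date="2015-01-15"),
                           frost_row(date="2015-04-10")])
        out, rep = curation.filter_midwinter(df)
        assert len(out) == 1
        assert rep["dropped_out_of_window"] == 1

    def test_southern_hemisphere_window(self):
        df = pd.DataFrame([frost_row(date="2015-07-15", lat=-40.0),
                           frost_row(date="2015-01-15", lat=-40.0)])
        out, _ = curation.filter_midwinter(df)
        assert len(out) == 1
        assert pd.to_datetime(out["date"].iloc[0]).month == 7

    def test_dateless_rows_dropped_and_counted(self):
        rows = [frost_row(date="2015-01-15")] * 7 + [frost_row(date=None)] * 3
        out, rep = curation.filter_midwinter(pd.DataFrame(rows))
        assert len(out) == 7
        assert rep["dropped_no_date"] == 3

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            curation.filter_midwinter(
                pd.DataFrame([frost_row()]),
                window={"N": frozenset(), "S": frozenset({6})})


class TestRateScreen:
    @pytest.mark.parametrize("rate,kept", [
        (0.1, False), (0.2, True), (5.0, True), (9.0, True), (9.5, False)])
    def test_bounds_inclusive(self, rate, kept):
        out, _ = curation.screen_rates(pd.DataFrame([frost_row(rate=rate)]))
        assert (len(out) == 1) is kept

    def test_missing_rate_retained_flagged(self):
        out, rep = curation.screen_rates(
            pd.DataFrame([frost_row(rate=None)]))
        assert len(out) == 1
        assert out["rate_missing"].iloc[0]
        assert rep["missing_rate_flagged"] == 1


class TestElSigmoid:
    def curve(self, lt50=-20.0, baseline=10.0, plateau=90.0, s=0.5,
              temps=None):
        T = np.array(temps if temps is not None
                     else [-40, -32, -26, -22, -18, -14, -8, 0], dtype=float)
        rel = baseline + (plateau - baseline) / (1 + np.exp(s * (T - lt50)))
        return T, rel

    def test_noiseless_recovery(self):
        T, rel = self.curve()
        fit = curation.fit_el_sigmoid(T, rel)
        assert fit.converged
        assert fit.lt50 == pytest.approx(-20.0, abs=1e-6)
        assert fit.baseline < fit.plateau

    def test_noisy_recovery_monte_carlo(self):
        """Mean recovered LT50 within +/-0.5 degC at 3% REL noise."""
        rng = np.random.default_rng(7)
        hats = []
        for _ in range(200):
            T, rel = self.curve()
            noisy = np.clip(rel + 3.0 * rng.standard_normal(len(T)), 0, 100)
            hats.append(curation.fit_el_sigmoid(T, noisy).lt50)
        assert np.mean(hats) == pytest.approx(-20.0, abs=0.5)

    def test_flat_curve_errors(self):
        T = np.linspace(-30, 0, 8)
        with pytest.raises(ValueError, match="flat"):
            curation.fit_el_sigmoid(T, np.full(8, 12.0))

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="5 points"):
            curation.fit_el_sigmoid([-30, -20, -10, 0], [90, 60, 30, 10])

    def test_duplicate_temperatures(self):
        with pytest.raises(ValueError, match="distinct"):
            curation.fit_el_sigmoid([-30, -20, -20, -10, 0],
                                    [90, 60, 50, 30, 10])


class TestFrostSelection:
    def test_el_branch_beats_el_leaf(self):
        df = pd.DataFrame([frost_row(organ="branch", method="EL", value=-30),
                           frost_row(organ="leaf", method="EL", value=-25)])
        out = curation.select_frost_value(df)
        assert out["lt50"].iloc[0] == -30
        assert out["lt50_category"].iloc[0] == 1

    def test_el_bud_beats_vs_branch(self):
        df = pd.DataFrame([frost_row(organ="branch", method="VS", value=-20),
                           frost_row(organ="bud", method="EL", value=-18)])
        out = curation.select_frost_value(df)
        assert out["lt50"].iloc[0] == -18
        assert out["lt50_category"].iloc[0] == 2

    def test_single_vs_leaf_is_category_six(self):
        df = pd.DataFrame([frost_row(organ="leaf", method="VS", value=-8)])
        out = curation.select_frost_value(df)
        assert out["lt50"].iloc[0] == -8
        assert out["lt50_category"].iloc[0] == 6

    def test_cell_averaging(self):
        df = pd.DataFrame([frost_row(value=-28), frost_row(value=-32)])
        out = curation.select_frost_value(df)
        assert out["lt50"].iloc[0] == pytest.approx(-30.0)

    def test_category_is_minimum_available(self):
        df = pd.DataFrame([
            frost_row(organ="leaf", method="VS", value=-5),
            frost_row(organ="bud", method="VS", value=-10),
            frost_row(organ="branch", method="VS", value=-15)])
        out = curation.select_frost_value(df)
        assert out["lt50_category"].iloc[0] == 3

    @settings(max_examples=20, deadline=None)
    @given(perm=st.permutations(range(6)))
    def test_order_independence(self, perm):
        rows = [frost_row(organ=o, method=m, value=v)
                for (o, m, v) in [("branch", "EL", -30), ("bud", "EL", -20),
                                  ("leaf", "VS", -5), ("branch", "VS", -25),
                                  ("bud", "VS", -15), ("leaf", "EL", -10)]]
        df = pd.DataFrame([rows[i] for i in perm])
        out = curation.select_frost_value(df)
        assert out["lt50"].iloc[0] == -30
        assert out["lt50_category"].iloc[0] == 1

    def test_idempotent_on_selected_output(self):
        df = pd.DataFrame([frost_row(value=-28), frost_row(value=-32),
                           frost_row(organ="leaf", method="VS", value=-3)])
        once = curation.select_frost_value(df)
        again = curation.select_frost_value(pd.DataFrame([
            frost_row(value=once["lt50"].iloc[0])]))
        assert again["lt50"].iloc[0] == once["lt50"].iloc[0]


class TestDroughtCuration:
    def drought_row(self, species="Pinus nigra", organ="stem",
                    technique="centrifuge", shape="sigmoid", p50=-5.0,
                    tlp=None):
        return {"species": species, "organ": organ, "technique": technique,
                "curve_shape": shape, "p50_MPa": p50, "psi_tlp_MPa": tlp}

    def test_r_shaped_removed(self):
        df = pd.DataFrame([self.drought_row(shape="r_shaped"),
                           self.drought_row(shape="sigmoid")])
        out, rep = curation.filter_curve_shape(df)
        assert len(out) == 1
        assert rep["dropped_r_shaped"] == 1

    def test_fixture_counts(self):
        rows = [self.drought_row(shape="r_shaped")] * 4 + \
               [self.drought_row(shape="sigmoid")] * 6
        out, _ = curation.filter_curve_shape(pd.DataFrame(rows))
        assert len(out) == 6

    def test_tier1_mean_of_centrifuge_and_optical(self):
        df = pd.DataFrame([self.drought_row(technique="centrifuge", p50=-5.1),
                           self.drought_row(technique="optical", p50=-4.9)])
        out = curation.select_p50_value(df)
        assert out["p50"].iloc[0] == pytest.approx(-5.0)
        assert out["p50_source"].iloc[0] == "tier1"

    def test_bench_beats_air_injection(self):
        df = pd.DataFrame([
            self.drought_row(technique="bench_dehydration", p50=-3.0),
            self.drought_row(technique="air_injection", p50=-2.0)])
        out = curation.select_p50_value(df)
        assert out["p50"].iloc[0] == pytest.approx(-3.0)
        assert out["p50_source"].iloc[0] == "tier2"

    def test_air_injection_only_is_tier4(self):
        df = pd.DataFrame([self.drought_row(technique="air_injection",
                                            p50=-2.4)])
        out = curation.select_p50_value(df)
        assert out["p50"].iloc[0] == pytest.approx(-2.4)
        assert out["p50_source"].iloc[0] == "tier4"

    def test_tlp_filter(self):
        df = pd.DataFrame([
            {"species": "A a", "p50": -1.2, "psi_tlp": -1.8},
            {"species": "B b", "p50": -3.5, "psi_tlp": -1.8},
            {"species": "C c", "p50": -2.0, "psi_tlp": np.nan}])
        out, rep = curation.tlp_consistency_filter(df)
        assert set(out["species"]) == {"B b", "C c"}
        assert rep["dropped_p50_above_tlp"] == 1
        assert bool(out.loc[out["species"] == "C c", "tlp_unchecked"].iloc[0])


class TestMerge:
    def test_set_arithmetic(self):
        frost = pd.DataFrame({"species": [f"A sp{i}" for i in range(5)],
                              "lt50": -10.0})
        drought = pd.DataFrame(
            {"species": [f"A sp{i}" for i in range(2, 9)], "p50": -3.0})
        merged, rep = curation.merge_species_table(frost, drought)
        assert len(merged) == 9
        assert rep["frost_drought_overlap"] == 3

    def test_canonicalization_joins(self):
        frost = pd.DataFrame({"species": ["quercus  ilex"], "lt50": [-12.0]})
        drought = pd.DataFrame({"species": ["Quercus ilex"], "p50": [-6.0]})
        merged, rep = curation.merge_species_table(frost, drought)
        assert len(merged) == 1
        assert merged["species"].iloc[0] == "Quercus ilex"

    def test_duplicate_species_raises(self):
        frost = pd.DataFrame({"species": ["Pinus nigra", "Pinus nigra"],
                              "lt50": [-20.0, -22.0]})
        with pytest.raises(ValueError, match="Pinus nigra"):
            curation.merge_species_table(frost, None)


class TestEndToEnd:
    def test_row_count_conservation(self):
        rows = ([frost_row()] * 5 + [frost_row(date="2015-06-01")] * 2
                + [frost_row(rate=0.05)] * 2 + [frost_row(date=None)])
        table, rep = curation.curate_frost(pd.DataFrame(rows))
        mid = rep["midwinter"]
        assert mid["input_rows"] == mid["kept_rows"] + \
            mid["dropped_no_date"] + mid["dropped_out_of_window"]
        rs = rep["rate_screen"]
        assert rs["input_rows"] == rs["kept_rows"] + \
            rs["dropped_rate_out_of_bounds"]

    def test_category_counts_sum_to_species_total(self):
        rng = np.random.default_rng(3)
        organs = ["branch", "bud", "leaf"]
        methods = ["EL", "VS"]
        rows = []
        for i in range(40):
            for _ in range(int(rng.integers(1, 4))):
                rows.append(frost_row(
                    species=f"Genus{i // 5} sp{i}",
                    organ=organs[int(rng.integers(3))],
                    method=methods[int(rng.integers(2))],
                    value=float(-5 - 30 * rng.random())))
        table, rep = curation.curate_frost(pd.DataFrame(rows))
        assert sum(rep["category_counts"].values()) == rep["species"]
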