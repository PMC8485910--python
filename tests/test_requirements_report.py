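"""Demographically weighted targets, adequacy reporting and Δ comparison."""

import numpy as np
import pandas as pd
import pytest

from delta import (
    DataValidationError,
    Scenario,
    adequacy_report,
    compare_scenarios,
    load_dataset,
    run,
    weighted_targets,
)
from delta.nutrition import NutrientSupply
from delta.requirements_report import format_report


def _drv(rows):
    return pd.DataFrame(rows, columns=[
        "nutrient_id", "sex", "age_group", "target", "lower_safe", "upper_safe",
        "unit", "alt_target_vegetarian", "alt_target_vegan",
    ])


def _demo(pops):
    """pops: {(region, sex, age): population} at year 2018."""
    return pd.DataFrame([
        {"region_id": r, "sex": s, "age_group": a, "year": 2018, "population": p}
        for (r, s, a), p in pops.items()
    ])


def _supply(**kw) -> NutrientSupply:
    s = pd.Series(kw, dtype=float)
    return NutrientSupply(supply=s, provenance=pd.DataFrame([kw], index=["all"]))


class TestWeightedTargets:
    def test_uniform_drv_is_returned_unchanged(self):
        drv = _drv([["ca", s, a, 1000.0, np.nan, np.nan, "mg", np.nan, np.nan]
                    for s in "FM" for a in ("child", "adult")])
        demo = _demo({("r", s, a): p for s, a, p in
                      [("F", "child", 10), ("F", "adult", 70), ("M", "child", 15),
                       ("M", "adult", 40)]})
        out = weighted_targets(drv, demo, 2018)
        assert out.loc["ca", "target"] == pytest.approx(1000.0)

    def test_two_strata_weighted_mean(self):
        drv = _drv([
            ["ca", "F", "a", 800.0, np.nan, np.nan, "mg", np.nan, np.nan],
            ["ca", "M", "a", 1200.0, np.nan, np.nan, "mg", np.nan, np.nan],
        ])
        demo = _demo({("r", "F", "a"): 1.0, ("r", "M", "a"): 3.0})
        out = weighted_targets(drv, demo, 2018)
        assert out.loc["ca", "target"] == pytest.approx(1100.0)

    def test_regions_contribute_weights_only(self):
        drv = _drv([
            ["ca", "F", "a", 800.0, np.nan, np.nan, "mg", np.nan, np.nan],
            ["ca", "M", "a", 1200.0, np.nan, np.nan, "mg", np.nan, np.nan],
        ])
        # same sex/age totals split across two regions
        demo = _demo({("r1", "F", "a"): 0.5, ("r2", "F", "a"): 0.5,
                      ("r1", "M", "a"): 2.0, ("r2", "M", "a"): 1.0})
        out = weighted_targets(drv, demo, 2018)
        assert out.loc["ca", "target"] == pytest.approx(1100.0)

    def test_vegan_mode_substitutes_alternate_targets_before_weighting(self):
        drv = _drv([
            ["iron", "F", "a", 10.0, np.nan, np.nan, "mg", 15.0, 15.0],
            ["iron", "M", "a", 10.0, np.nan, np.nan, "mg", 15.0, 15.0],
        ])
        demo = _demo({("r", "F", "a"): 1.0, ("r", "M", "a"): 1.0})
        omni = weighted_targets(drv, demo, 2018, "omnivore")
        vegan = weighted_targets(drv, demo, 2018, "vegan")
        assert vegan.loc["iron", "target"] == pytest.approx(1.5 * omni.loc["iron", "target"])

    def test_bounds_omitted_when_any_stratum_lacks_them(self):
        drv = _drv([
            ["ca", "F", "a", 1000.0, 700.0, 2500.0, "mg", np.nan, np.nan],
            ["ca", "M", "a", 1000.0, np.nan, 2500.0, "mg", np.nan, np.nan],
        ])
        demo = _demo({("r", "F", "a"): 1.0, ("r", "M", "a"): 1.0})
        out = weighted_targets(drv, demo, 2018)
        assert np.isnan(out.loc["ca", "lower_safe"])
        assert out.loc["ca", "upper_safe"] == pytest.approx(2500.0)

    def test_missing_stratum_is_an_error_naming_it(self):
        drv = _drv([["ca", "F", "a", 1000.0, np.nan, np.nan, "mg", np.nan, np.nan]])
        demo = _demo({("r", "F", "a"): 1.0, ("r", "M", "a"): 1.0})
        with pytest.raises(DataValidationError, match="'ca'.*M"):
            weighted_targets(drv, demo, 2018)

    def test_weighted_target_within_stratum_range(self, mini_world):
        """Convexity: the global target lies inside [min, max] of stratum DRVs."""
        ds = load_dataset(mini_world(2))
        year = int(ds.demographics["year"].min())
        out = weighted_targets(ds.drv, ds.demographics, year)
        by_nutrient = ds.drv.groupby("nutrient_id")["target"]
        for nid, row in out.iterrows():
            assert by_nutrient.min()[nid] - 1e-9 <= row["target"] <= by_nutrient.max()[nid] + 1e-9

    def test_unresolved_auto_mode_rejected(self):
        with pytest.raises(ValueError):
            weighted_targets(_drv([]), _demo({("r", "F", "a"): 1.0}), 2018, "auto")


def _targets(**rows):
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("nutrient_id")


class TestAdequacyReport:
    def test_gap_is_shortfall_as_percent_of_target(self):
        targets = _targets(ca=dict(target=1000.0, lower_safe=700.0,
                                   upper_safe=2500.0, unit="mg"))
        report = adequacy_report(_supply(ca=0.64 * 1000.0), targets)
        row = report.set_index("nutrient_id").loc["ca"]
        assert row["gap_pct"] == pytest.approx(36.0)
        assert row["pct_of_target"] == pytest.approx(64.0)
        assert bool(row["material"])

    def test_supply_at_target_has_no_gap_or_excess(self):
        targets = _targets(ca=dict(target=1000.0, lower_safe=700.0,
                                   upper_safe=2500.0, unit="mg"))
        row = adequacy_report(_supply(ca=1000.0), targets).iloc[0]
        assert row["gap_pct"] == 0.0 and row["excess_pct"] == 0.0

    def test_excess_above_upper_safe_limit(self):
        targets = _targets(en=dict(target=2000.0, lower_safe=np.nan,
                                   upper_safe=3000.0, unit="kcal"))
        row = adequacy_report(_supply(en=1.10 * 3000.0), targets).iloc[0]
        assert row["excess_pct"] == pytest.approx(10.0)
        assert row["gap_pct"] == 0.0

    def test_small_gap_is_not_material(self):
        targets = _targets(ca=dict(target=100.0, lower_safe=np.nan,
                                   upper_safe=np.nan, unit="mg"))
        row = adequacy_report(_supply(ca=96.0), targets, material_threshold_pct=5).iloc[0]
        assert row["gap_pct"] == pytest.approx(4.0)
        assert not row["material"]

    def test_gap_and_excess_never_both_positive(self, mini_world):
        ds = load_dataset(mini_world(3))
        res = run(ds, Scenario())
        both = res.nutrient_report[
            (res.nutrient_report["gap_pct"] > 0) & (res.nutrient_report["excess_pct"] > 0)
        ]
        assert both.empty

    def test_missing_target_emits_row_without_gap(self, caplog):
        targets = _targets(ca=dict(target=1000.0, lower_safe=np.nan,
                                   upper_safe=np.nan, unit="mg"))
        with caplog.at_level("WARNING"):
            report = adequacy_report(_supply(ca=900.0, mystery=5.0), targets)
        row = report.set_index("nutrient_id").loc["mystery"]
        assert np.isnan(row["gap_pct"]) and not row["material"]
        assert len(report) == 2

    def test_display_rounding_blanks_immaterial_gaps(self):
        targets = _targets(ca=dict(target=100.0, lower_safe=np.nan,
                                   upper_safe=np.nan, unit="mg"))
        disp = format_report(adequacy_report(_supply(ca=96.0), targets))
        assert np.isnan(disp.iloc[0]["gap_pct"])


class TestCompareScenarios:
    def _reports(self, analytic_dataset, analytic_shares):
        a = run(analytic_dataset, Scenario(name="a"), shares=analytic_shares)
        b = run(analytic_dataset, Scenario(name="b", in_home_waste_multiplier=0.5),
                shares=analytic_shares)
        return a, b

    def test_identical_runs_give_zero_deltas(self, analytic_dataset, analytic_shares):
        a, _ = self._reports(analytic_dataset, analytic_shares)
        out = compare_scenarios(a.nutrient_report, a.mass_report,
                                a.nutrient_report, a.mass_report)
        assert (out["nutrients"]["delta_supply"] == 0).all()
        assert (out["groups"]["delta_production_t"] == 0).all()

    def test_deltas_equal_oracle_subtraction(self, analytic_dataset, analytic_shares):
        a, b = self._reports(analytic_dataset, analytic_shares)
        out = compare_scenarios(a.nutrient_report, a.mass_report,
                                b.nutrient_report, b.mass_report)
        merged = out["nutrients"].set_index("nutrient_id")
        ra = a.nutrient_report.set_index("nutrient_id")
        rb = b.nutrient_report.set_index("nutrient_id")
        for n in merged.index:
            assert merged.loc[n, "delta_supply"] == pytest.approx(
                rb.loc[n, "supply"] - ra.loc[n, "supply"], rel=1e-12
            )
            assert merged.loc[n, "delta_gap_pct"] == pytest.approx(
                rb.loc[n, "gap_pct"] - ra.loc[n, "gap_pct"], abs=1e-12
            )

    def test_halved_supply_shows_as_negative_delta(self, analytic_dataset, analytic_shares):
        a, _ = self._reports(analytic_dataset, analytic_shares)
        halved = a.nutrient_report.copy()
        halved.loc[halved["nutrient_id"] == "calcium", "supply"] *= 0.5
        out = compare_scenarios(a.nutrient_report, a.mass_report, halved, a.mass_report)
        row = out["nutrients"].set_index("nutrient_id").loc["calcium"]
        ca = a.nutrient_report.set_index("nutrient_id").loc["calcium", "supply"]
        assert row["delta_supply"] == pytest.approx(-0.5 * ca)

    def test_mismatched_nutrient_sets_listed_in_error(self, analytic_dataset, analytic_shares):
        a, _ = self._reports(analytic_dataset, analytic_shares)
        trimmed = a.nutrient_report[a.nutrient_report["nutrient_id"] != "iron"]
        with pytest.raises(DataValidationError, match="iron"):
            compare_scenarios(a.nutrient_report, a.mass_report, trimmed, a.mass_report)
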