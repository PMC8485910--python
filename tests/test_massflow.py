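"""The deduction cascade: distribution, feed, nonfood, full runs."""

import numpy as np
import pandas as pd
import pytest

from delta import (
    DataValidationError,
    InfeasibleScenarioError,
    ResolvedScenario,
    Scenario,
    compute_feed_use,
    compute_nonfood_use,
    distribute_to_items,
    global_waste_fractions,
    load_dataset,
    run,
    run_mass_balance,
)
from delta.baseline import BaselineShares
from delta.config import ModelConfig


def _shares(item_share, item_group, **kw) -> BaselineShares:
    items = list(item_share)
    defaults = dict(
        feed_fraction={i: 0.0 for i in items},
        loss_fraction={i: 0.0 for i in items},
        nonfood_fraction={i: 0.0 for i in items},
        baseline_production={i: 1.0 for i in items},
        baseline_population=1000.0,
        baseline_year=2018,
    )
    defaults.update(kw)
    return BaselineShares(item_share=item_share, item_group=item_group, **defaults)


class TestDistributeToItems:
    def test_proportional_split(self):
        shares = _shares({"apple": 0.6, "banana": 0.4},
                         {"apple": "fruit", "banana": "fruit"})
        out = distribute_to_items({"fruit": 100.0}, shares)
        assert out == {"apple": pytest.approx(60.0), "banana": pytest.approx(40.0)}
        assert sum(out.values()) == pytest.approx(100.0, rel=1e-15)

    def test_zero_group_gives_zero_items(self):
        shares = _shares({"apple": 0.6, "banana": 0.4},
                         {"apple": "fruit", "banana": "fruit"})
        assert distribute_to_items({"fruit": 0.0}, shares) == {"apple": 0.0, "banana": 0.0}

    def test_group_absent_from_shares_is_an_error(self):
        shares = _shares({"apple": 1.0}, {"apple": "fruit"})
        with pytest.raises(DataValidationError, match="nuts"):
            distribute_to_items({"nuts": 5.0}, shares)


class TestComputeFeedUse:
    ATTR = {("maize", "beef"): 60.0, ("maize", "dairy"): 40.0, ("soy", "dairy"): 10.0}

    def test_unit_ratios_reproduce_baseline(self):
        feed = compute_feed_use({"maize": 500.0, "soy": 50.0}, self.ATTR,
                                {"beef": 1.0, "dairy": 1.0})
        assert feed["maize"] == pytest.approx(100.0)
        assert feed["soy"] == pytest.approx(10.0)

    def test_zero_ratios_zero_all_feed(self):
        feed = compute_feed_use({"maize": 500.0, "soy": 50.0}, self.ATTR,
                                {"beef": 0.0, "dairy": 0.0})
        assert feed == {"maize": 0.0, "soy": 0.0}

    def test_mixed_ratios_sum_per_item(self):
        # meat gone, dairy scaled 1.2: maize feed = 0*60 + 1.2*40
        feed = compute_feed_use({"maize": 500.0, "soy": 50.0}, self.ATTR,
                                {"beef": 0.0, "dairy": 1.2})
        assert feed["maize"] == pytest.approx(48.0)
        assert feed["soy"] == pytest.approx(12.0)

    def test_demand_exceeding_item_production_names_the_item(self):
        with pytest.raises(InfeasibleScenarioError, match="maize"):
            compute_feed_use({"maize": 80.0, "soy": 50.0}, self.ATTR,
                             {"beef": 1.0, "dairy": 1.0})


class TestComputeNonfoodUse:
    def test_per_capita_constant_scales_with_population(self):
        out = compute_nonfood_use({"x": 100.0}, 1000.0, 2000.0, "per_capita_constant")
        assert out["x"] == pytest.approx(200.0)

    def test_equal_populations_leave_tonnage_unchanged(self):
        out = compute_nonfood_use({"x": 100.0}, 1000.0, 1000.0, "per_capita_constant")
        assert out["x"] == pytest.approx(100.0)

    def test_proportional_mode_follows_production(self):
        out = compute_nonfood_use(
            {"x": 100.0}, 1000.0, 1000.0, "proportional_to_production",
            item_production={"x": 1120.0}, nonfood_fraction={"x": 0.1},
        )
        assert out["x"] == pytest.approx(112.0)


class TestFullCascade:
    def test_single_item_hand_cascade(self, analytic_dataset, analytic_shares):
        """1000 t − 200 feed − 100 loss − 50 nonfood = 650; ×0.9 edible = 585;
        ×0.9 after in-home waste = 526.5 t consumed."""
        result = run(analytic_dataset, Scenario(), shares=analytic_shares).mass
        wheat = result.items.loc["wheat"]
        assert wheat["feed_t"] == pytest.approx(200.0, rel=1e-12)
        assert wheat["supply_chain_loss_t"] == pytest.approx(100.0, rel=1e-12)
        assert wheat["nonfood_t"] == pytest.approx(50.0, rel=1e-12)
        assert wheat["consumed_edible_t"] == pytest.approx(526.5, rel=1e-12)

    def test_per_capita_conversion(self, analytic_dataset, analytic_shares):
        """7.3 t/yr over 10,000 people is 2.0 g/person/day; the analytic
        world's wheat follows the same conversion."""
        result = run(analytic_dataset, Scenario(), shares=analytic_shares).mass
        assert result.population == 10_000
        wheat = result.items.loc["wheat"]
        assert wheat["per_capita_g_day"] == pytest.approx(
            wheat["consumed_edible_t"] * 1e6 / 10_000 / 365, rel=1e-12
        )
        assert 7.3e6 / 10_000 / 365 == pytest.approx(2.0)

    def test_zero_waste_multipliers_zero_both_waste_streams(
        self, analytic_dataset, analytic_shares
    ):
        sc = Scenario(supply_chain_waste_multiplier=0.0, in_home_waste_multiplier=0.0)
        result = run(analytic_dataset, sc, shares=analytic_shares).mass
        assert (result.items["supply_chain_loss_t"] == 0).all()
        assert (result.items["in_home_waste_t"] == 0).all()

    def test_mass_conservation_identity(self, mini_world):
        for seed in range(3):
            ds = load_dataset(mini_world(seed))
            result = run(ds, Scenario(in_home_waste_multiplier=1.3)).mass
            total = result.items[[
                "feed_t", "supply_chain_loss_t", "nonfood_t",
                "inedible_t", "in_home_waste_t", "consumed_edible_t",
            ]].sum(axis=1)
            np.testing.assert_allclose(
                total, result.items["production_t"], rtol=1e-6
            )

    @pytest.mark.parametrize("multiplier_field", [
        "supply_chain_waste_multiplier", "in_home_waste_multiplier",
    ])
    def test_consumed_mass_monotone_in_waste_multipliers(
        self, analytic_dataset, analytic_shares, multiplier_field
    ):
        consumed = []
        for m in (0.0, 0.5, 1.0, 1.5):
            sc = Scenario(**{multiplier_field: m})
            result = run(analytic_dataset, sc, shares=analytic_shares).mass
            consumed.append(result.items["consumed_edible_t"].sum())
        assert all(a >= b - 1e-12 for a, b in zip(consumed, consumed[1:]))

    def test_proportional_mode_is_linear_in_uniform_scaling(self, mini_world):
        ds = load_dataset(mini_world(0))
        k = 1.37
        base = run(ds, Scenario(nonfood_mode="proportional_to_production")).mass
        groups = sorted(base.items["group_id"].unique())
        scaled_sc = Scenario(
            nonfood_mode="proportional_to_production",
            groups={g: {"multiplier": k} for g in groups},
        )
        scaled = run(ds, scaled_sc).mass
        for col in ("production_t", "feed_t", "supply_chain_loss_t", "nonfood_t",
                    "inedible_t", "in_home_waste_t", "consumed_edible_t"):
            np.testing.assert_allclose(
                scaled.items[col], base.items[col] * k, rtol=1e-9
            )

    def test_infeasible_feed_demand_raises_with_item_name(
        self, analytic_dataset, analytic_shares
    ):
        # quadruple dairy: wheat feed demand 800 t, but plants shrink to 10%
        sc = Scenario(groups={
            "dairy": {"multiplier": 4.0}, "plants": {"multiplier": 0.1},
        })
        with pytest.raises(InfeasibleScenarioError, match="wheat"):
            run(analytic_dataset, sc, shares=analytic_shares)

    def test_excess_in_home_waste_multiplier_is_infeasible(
        self, analytic_dataset, analytic_shares
    ):
        sc = Scenario(in_home_waste_multiplier=11.0)   # 0.1 × 11 > 1
        with pytest.raises(InfeasibleScenarioError, match="waste fraction"):
            run(analytic_dataset, sc, shares=analytic_shares)


def test_explicit_feed_attribution_file_redirects_feed(tmp_path):
    """A feed_attribution.csv in the data directory overrides the
    proportional fallback: feed pinned to one animal group vanishes when
    that group's production is zeroed."""
    from delta import make_world, run_directory
    from delta.synthetic_fixtures import WorldSpec

    d = make_world(WorldSpec(seed=11, shape="mini", n_groups=6, n_items=12), tmp_path)
    ds = load_dataset(d)
    animal = sorted(ds.groups.index[ds.groups["origin"] == "animal"])
    assert len(animal) == 2
    fed = run_directory(d).mass.items
    feed_item = fed[fed["feed_t"] > 0].index[0]
    (d / "feed_attribution.csv").write_text(
        "feed_item_id,animal_group_id,tons\n"
        f"{feed_item},{animal[0]},1.0\n"
    )
    scenario = d / "no_first_animal.yaml"
    # proportional nonfood: a zeroed group keeps no absolute nonfood demand
    scenario.write_text(
        f"groups:\n  {animal[0]}: {{multiplier: 0}}\n"
        "nonfood_mode: proportional_to_production\n"
    )
    result = run_directory(d, scenario)
    assert result.mass.items.loc[feed_item, "feed_t"] == 0.0


def test_global_waste_fractions_population_weighting(analytic_dataset):
    # north 0.15 / south 0.05 with equal populations -> 0.10
    out = global_waste_fractions(
        analytic_dataset.waste, analytic_dataset.demographics, 2018
    )
    assert out["plants"] == pytest.approx(0.10)
    assert out["dairy"] == pytest.approx(0.10)


def test_unsupported_waste_collapse_mode_rejected(analytic_dataset):
    cfg = ModelConfig(massflow={"waste_collapse": "supply"})
    with pytest.raises(NotImplementedError):
        global_waste_fractions(
            analytic_dataset.waste, analytic_dataset.demographics, 2018, cfg
        )
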