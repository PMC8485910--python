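"""The deduction cascade: farm-gate production to per-capita daily allocation.

Per item the cascade removes, in order: animal feed, supply-chain loss,
nonfood use, the inedible portion, and in-home waste.  Feed, loss and
nonfood fractions are all defined on farm-gate production (not on
sequential residuals), so the order within that trio cannot change the
result; the inedible fraction applies to what reaches consumers and the
in-home waste fraction to the edible mass that remains.  Mass is conserved
at every step and any negative intermediate is an error, never a clamp —
an infeasible scenario should be visible, not silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baseline import BaselineShares, total_population
from .config import DEFAULT_CONFIG, ModelConfig
from .data_io import DataValidationError, Dataset
from .scenario import ResolvedScenario


class InfeasibleScenarioError(DataValidationError):
    """A cascade stage went negative; the message names item and stage."""


@dataclass
class MassFlowResult:
    """Per-item cascade components (tons/yr) plus the scenario population.

    ``items`` is indexed by item_id with columns group_id, production_t,
    feed_t, supply_chain_loss_t, nonfood_t, inedible_t, in_home_waste_t,
    consumed_edible_t, per_capita_g_day.  The conservation identity
    production = feed + loss + nonfood + inedible + in-home waste + consumed
    holds within 1e-6 relative per item.
    """

    items: pd.DataFrame
    population: float
    population_year: int

    @property
    def per_capita_g_day(self) -> pd.Series:
        return self.items["per_capita_g_day"]

    def group_production(self) -> pd.Series:
        return self.items.groupby("group_id")["production_t"].sum()


def distribute_to_items(
    group_production: dict[str, float], shares: BaselineShares
) -> dict[str, float]:
    """Split each group's production across its items by baseline shares."""
    missing = sorted(set(group_production) - set(shares.group_production()))
    if missing:
        raise DataValidationError(f"group(s) {missing} absent from baseline shares")
    return {
        item: group_production[shares.item_group[item]] * shares.item_share[item]
        for item in shares.item_share
        if shares.item_group[item] in group_production
    }


def compute_feed_use(
    item_production: dict[str, float],
    feed_attribution: dict[tuple[str, str], float],
    animal_production_ratio: dict[str, float],
) -> dict[str, float]:
    """Feed demand per item: baseline attribution scaled by animal-group ratios."""
    if any(r < 0 for r in animal_production_ratio.values()):
        raise DataValidationError("animal production ratios must be >= 0")
    feed: dict[str, float] = {item: 0.0 for item in item_production}
    for (item, group), tons in feed_attribution.items():
        ratio = animal_production_ratio.get(group, 0.0)
        feed[item] = feed.get(item, 0.0) + tons * ratio
    for item, demand in feed.items():
        avail = item_production.get(item, 0.0)
        if demand > avail * (1 + 1e-9):
            raise InfeasibleScenarioError(
                f"feed demand {demand:.6g} t for item '{item}' exceeds its "
                f"production {avail:.6g} t"
            )
    return feed


def compute_nonfood_use(
    baseline_nonfood: dict[str, float],
    baseline_population: float,
    scenario_population: float,
    mode: str,
    item_production: dict[str, float] | None = None,
    nonfood_fraction: dict[str, float] | None = None,
) -> dict[str, float]:
    """Nonfood (biofuel, industrial) use per item under the scenario.

    ``per_capita_constant`` keeps per-capita nonfood use at its baseline
    level, scaling tonnage with population; ``proportional_to_production``
    keeps the baseline nonfood fraction of each item's production.
    """
    if baseline_population <= 0 or scenario_population <= 0:
        raise DataValidationError("populations must be positive")
    if mode == "per_capita_constant":
        ratio = scenario_population / baseline_population
        return {item: t * ratio for item, t in baseline_nonfood.items()}
    if mode == "proportional_to_production":
        if item_production is None or nonfood_fraction is None:
            raise DataValidationError(
                "proportional_to_production mode needs item production and fractions"
            )
        return {
            item: nonfood_fraction.get(item, 0.0) * prod
            for item, prod in item_production.items()
        }
    raise ValueError(f"unknown nonfood mode '{mode}'")


def global_waste_fractions(
    waste: pd.DataFrame,
    demographics: pd.DataFrame,
    year: int,
    config: ModelConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """Collapse regional in-home waste fractions to one fraction per group.

    Regions are weighted by their population at the scenario year (the model
    is global; a supply-weighted collapse is not implemented).
    """
    if config.massflow.waste_collapse != "population":
        raise NotImplementedError("only population-weighted waste collapse is available")
    by_region = pd.DataFrame({"population": _region_population(demographics, year)})
    merged = waste.merge(by_region, left_on="region_id", right_index=True, how="left")
    if merged["population"].isna().any():
        missing = sorted(merged.loc[merged["population"].isna(), "region_id"].unique())
        raise DataValidationError(f"no demographics for region(s) {missing}")
    out: dict[str, float] = {}
    for gid, grp in merged.groupby("group_id"):
        total = grp["population"].sum()
        if total <= 0:
            raise DataValidationError(f"zero total population weighting waste for group '{gid}'")
        out[gid] = float((grp["waste_fraction"] * grp["population"]).sum() / total)
    return out


def _region_population(demographics: pd.DataFrame, year: int) -> pd.Series:
    from .baseline import population_by_stratum

    strata = population_by_stratum(demographics, year)
    return strata.groupby(level="region_id").sum()


def run_mass_balance(
    sc: ResolvedScenario,
    shares: BaselineShares,
    dataset: Dataset,
    config: ModelConfig = DEFAULT_CONFIG,
) -> MassFlowResult:
    """Execute the full cascade for a resolved scenario."""
    year = sc.population_year if sc.population_year is not None else shares.baseline_year
    population = total_population(dataset.demographics, year)
    if population <= 0:
        raise DataValidationError(f"population at year {year} is not positive")

    item_production = distribute_to_items(sc.group_production, shares)

    baseline_groups = shares.group_production()
    animal_groups = set(dataset.groups.index[dataset.groups["origin"] == "animal"])
    ratios = {
        g: (sc.group_production.get(g, 0.0) / baseline_groups[g])
        for g in animal_groups
        if baseline_groups.get(g, 0.0) > 0
    }
    feed = compute_feed_use(item_production, shares.feed_attribution, ratios)

    scm = sc.supply_chain_waste_multiplier
    baseline_nonfood = {
        item: shares.nonfood_fraction[item] * shares.baseline_production.get(item, 0.0)
        for item in shares.nonfood_fraction
    }
    nonfood = compute_nonfood_use(
        baseline_nonfood, shares.baseline_population, population,
        sc.nonfood_mode, item_production=item_production,
        nonfood_fraction=shares.nonfood_fraction,
    )

    group_waste = global_waste_fractions(dataset.waste, dataset.demographics, year, config)
    ihm = sc.in_home_waste_multiplier

    rows = []
    for item, prod in sorted(item_production.items()):
        group = shares.item_group[item]
        f = feed.get(item, 0.0)
        loss = shares.loss_fraction[item] * prod * scm
        nf = nonfood.get(item, 0.0)
        available = prod - f - loss - nf
        if available < -1e-9 * max(prod, 1.0):
            raise InfeasibleScenarioError(
                f"item '{item}': feed+loss+nonfood ({f + loss + nf:.6g} t) exceeds "
                f"production ({prod:.6g} t) at the consumer-availability stage"
            )
        available = max(available, 0.0)
        inedible_fraction = float(dataset.items.loc[item, "inedible_fraction"])
        inedible = inedible_fraction * available
        edible = available - inedible
        w_frac = group_waste.get(group, 0.0) * ihm
        if w_frac > 1:
            raise InfeasibleScenarioError(
                f"item '{item}': effective in-home waste fraction {w_frac:.4g} "
                "exceeds 1 after multiplication"
            )
        in_home = w_frac * edible
        consumed = edible - in_home
        rows.append({
            "item_id": item, "group_id": group, "production_t": prod,
            "feed_t": f, "supply_chain_loss_t": loss, "nonfood_t": nf,
            "inedible_t": inedible, "in_home_waste_t": in_home,
            "consumed_edible_t": consumed,
            "per_capita_g_day": consumed * 1e6 / population / config.massflow.days_per_year,
        })
    items = pd.DataFrame(rows).set_index("item_id")

    components = items[[
        "feed_t", "supply_chain_loss_t", "nonfood_t",
        "inedible_t", "in_home_waste_t", "consumed_edible_t",
    ]].sum(axis=1)
    rel = np.abs(components - items["production_t"]) / np.maximum(items["production_t"], 1e-300)
    bad = rel[(items["production_t"] > 0) & (rel > 1e-6)]
    if not bad.empty:
        raise AssertionError(
            f"mass conservation violated for item(s) {sorted(bad.index)}"
        )
    return MassFlowResult(items=items, population=population, population_year=year)
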