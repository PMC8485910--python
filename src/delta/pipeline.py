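"""End-to-end runner: dataset + scenario in, three reports out."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .baseline import BaselineShares, derive_feed_attribution, derive_shares
from .config import DEFAULT_CONFIG, ModelConfig
from .data_io import Dataset, Scenario, load_dataset, read_scenario
from .massflow import MassFlowResult, run_mass_balance
from .nutrition import NutrientSupply, nutrient_supply, nutrient_waste_accounting
from .requirements_report import adequacy_report, weighted_targets
from .scenario import ResolvedScenario, resolve_diet_mode, resolve_scenario


@dataclass
class RunResult:
    """Everything one scenario run produces."""

    scenario: ResolvedScenario
    shares: BaselineShares
    mass: MassFlowResult
    supply: NutrientSupply
    targets: pd.DataFrame
    nutrient_report: pd.DataFrame
    waste_report: pd.DataFrame

    @property
    def mass_report(self) -> pd.DataFrame:
        return self.mass.items.reset_index()


def prepare_baseline(
    dataset: Dataset,
    baseline_year: int | None = None,
    config: ModelConfig = DEFAULT_CONFIG,
    feed_attribution_input: pd.DataFrame | None = None,
) -> BaselineShares:
    """Derive shares and feed attribution; baseline year defaults to the
    year after the last balance-sheet year."""
    if baseline_year is None:
        baseline_year = int(dataset.balance["year"].max()) + 1
    shares = derive_shares(
        dataset.balance, dataset.demographics, baseline_year, config=config
    )
    groups = shares.group_production()
    animal = {
        g: groups.get(g, 0.0)
        for g in dataset.groups.index[dataset.groups["origin"] == "animal"]
    }
    shares.feed_attribution = derive_feed_attribution(
        shares, animal, attribution_input=feed_attribution_input
    )
    return shares


def run(
    dataset: Dataset,
    scenario: Scenario,
    config: ModelConfig = DEFAULT_CONFIG,
    shares: BaselineShares | None = None,
) -> RunResult:
    """Resolve and evaluate one scenario against a dataset."""
    if shares is None:
        shares = prepare_baseline(dataset, config=config)
    resolved = resolve_scenario(scenario, shares.group_production(), shares.baseline_year)
    resolved = resolve_diet_mode(resolved, shares.group_production(), dataset.groups, config)
    mass = run_mass_balance(resolved, shares, dataset, config)
    supply = nutrient_supply(mass.per_capita_g_day, dataset)
    targets = weighted_targets(
        dataset.drv, dataset.demographics, mass.population_year, resolved.diet_mode
    )
    report = adequacy_report(supply, targets, config.material_threshold_pct)
    waste = nutrient_waste_accounting(
        mass, dataset, targets, days_per_year=config.massflow.days_per_year
    )
    return RunResult(
        scenario=resolved, shares=shares, mass=mass, supply=supply,
        targets=targets, nutrient_report=report, waste_report=waste,
    )


def run_directory(
    data_dir: Path | str,
    scenario_path: Path | str | None = None,
    config: ModelConfig = DEFAULT_CONFIG,
) -> RunResult:
    """Load a data directory (and optional scenario file) and run it."""
    dataset = load_dataset(data_dir)
    if scenario_path is None:
        scenario = Scenario(name="baseline")
    else:
        scenario = read_scenario(scenario_path, known_groups=set(dataset.groups.index))
    attribution_path = Path(data_dir) / "feed_attribution.csv"
    attribution = pd.read_csv(attribution_path) if attribution_path.exists() else None
    shares = prepare_baseline(dataset, config=config, feed_attribution_input=attribution)
    return run(dataset, scenario, config=config, shares=shares)
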