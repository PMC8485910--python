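"""Per-capita nutrient supply and nutrient-waste accounting.

Supply of nutrient *n* is the digestibility-weighted sum over items of
``allocation_g_day / 100 × density(item, n)``; digestibility coefficients
differ from 1 only for protein and the indispensable amino acids.  Waste
accounting converts the edible share of supply-chain losses plus in-home
waste into the same nutrient terms (inedible matter carries no nutrients by
convention), so consumed supply plus wasted nutrients equals the supply a
zero-waste run would deliver — closure holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import DataValidationError, Dataset, WASTE_REPORT_COLUMNS
from .massflow import MassFlowResult


@dataclass
class NutrientSupply:
    """Per-capita daily nutrient amounts plus per-item provenance."""

    supply: pd.Series                # nutrient → amount/person/day
    provenance: pd.DataFrame         # item × nutrient contributions

    def __getitem__(self, nutrient_id: str) -> float:
        return float(self.supply[nutrient_id])


def nutrient_supply(allocations: pd.Series, dataset: Dataset) -> NutrientSupply:
    """Convert per-item allocations (g/person/day) into nutrient amounts."""
    allocations = allocations.astype(float)
    if (allocations < 0).any():
        bad = sorted(allocations.index[allocations < 0])
        raise DataValidationError(f"negative allocation for item(s) {bad}")
    missing = sorted(set(allocations.index) - set(dataset.densities.index))
    if missing:
        raise DataValidationError(f"item(s) without nutrient profile: {missing}")
    dens = dataset.densities.loc[allocations.index]
    dig = dataset.digestibility.loc[allocations.index]
    contributions = dens.mul(dig).mul(allocations / 100.0, axis=0)
    return NutrientSupply(supply=contributions.sum(axis=0), provenance=contributions)


def nutrient_waste_accounting(
    mass: MassFlowResult,
    dataset: Dataset,
    targets: pd.DataFrame,
    days_per_year: float = 365.0,
) -> pd.DataFrame:
    """Nutrients embodied in wasted and lost food, per person per day.

    Wasted mass per item is the edible fraction of its supply-chain loss
    plus its in-home waste (already edible); the same density ×
    digestibility conversion as consumed supply applies.  ``targets`` is a
    nutrient-indexed frame with a ``target`` column; a zero or missing
    target yields an empty ``pct_of_target`` cell rather than an error.
    """
    items = mass.items
    edible_frac = 1.0 - dataset.items.loc[items.index, "inedible_fraction"].astype(float)
    wasted_t = items["supply_chain_loss_t"] * edible_frac + items["in_home_waste_t"]
    wasted_g_day = wasted_t * 1e6 / mass.population / days_per_year

    wasted = nutrient_supply(wasted_g_day, dataset)
    origin = dataset.items.loc[items.index, "origin"]
    plant_items = origin[origin == "plant"].index
    animal_items = origin[origin == "animal"].index
    plant_amount = wasted.provenance.loc[wasted.provenance.index.isin(plant_items)].sum(axis=0)
    animal_amount = wasted.provenance.loc[wasted.provenance.index.isin(animal_items)].sum(axis=0)

    rows = []
    for nid in dataset.nutrient_ids:
        total = float(wasted.supply[nid])
        target = float(targets.loc[nid, "target"]) if nid in targets.index else np.nan
        pct = 100.0 * total / target if target and np.isfinite(target) and target > 0 else np.nan
        if total > 0:
            plant_share = 100.0 * float(plant_amount[nid]) / total
            animal_share = 100.0 * float(animal_amount[nid]) / total
        else:
            plant_share = animal_share = np.nan
        rows.append({
            "nutrient_id": nid, "wasted_amount": total, "pct_of_target": pct,
            "plant_share_pct": plant_share, "animal_share_pct": animal_share,
        })
    return pd.DataFrame(rows, columns=WASTE_REPORT_COLUMNS).sort_values(
        "nutrient_id"
    ).reset_index(drop=True)
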