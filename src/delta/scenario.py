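"""Scenario construction and transformation.

A :class:`~delta.data_io.Scenario` expresses user intent (multipliers,
zeroed groups, reallocations); resolution turns it into absolute per-group
farm-gate production for a given baseline, after which the transformations
here (uniform scaling, zero-with-compensation, remove-and-reallocate) are
plain arithmetic on that mapping.  The diet mode that governs which iron
and zinc targets apply is detected from the resolved productions unless the
user forces a mode.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .config import DEFAULT_CONFIG, ModelConfig
from .data_io import DataValidationError, Scenario, UnknownVocabularyError


@dataclass
class ResolvedScenario:
    """A scenario with every group's production made absolute (tons/yr)."""

    group_production: dict[str, float]
    supply_chain_waste_multiplier: float = 1.0
    in_home_waste_multiplier: float = 1.0
    population_year: int | None = None
    nonfood_mode: str = "per_capita_constant"
    diet_mode: str = "omnivore"
    name: str = "scenario"

    @property
    def total_biomass(self) -> float:
        return sum(self.group_production.values())


def resolve_scenario(
    sc: Scenario,
    baseline_group_production: dict[str, float],
    baseline_year: int,
) -> ResolvedScenario:
    """Turn user intent into absolute per-group production.

    Order of application: per-group tons/multipliers on the baseline, then
    zero-with-compensation, then remove-and-reallocate.
    """
    sc.validate_groups(set(baseline_group_production))
    production = dict(baseline_group_production)
    for gid, change in sc.groups.items():
        if change.tons is not None:
            production[gid] = float(change.tons)
        elif change.multiplier is not None:
            production[gid] = production[gid] * float(change.multiplier)
    resolved = ResolvedScenario(
        group_production=production,
        supply_chain_waste_multiplier=sc.supply_chain_waste_multiplier,
        in_home_waste_multiplier=sc.in_home_waste_multiplier,
        population_year=sc.population_year if sc.population_year is not None else baseline_year,
        nonfood_mode=sc.nonfood_mode,
        diet_mode=sc.diet_mode,
        name=sc.name,
    )
    if sc.zero_groups:
        resolved = zero_groups_with_compensation(
            resolved, set(sc.zero_groups), sc.compensation_factor
        )
    if sc.remove_group is not None:
        resolved = remove_and_reallocate(resolved, sc.remove_group, sc.recipients)
    return resolved


def scale_all_groups(base: ResolvedScenario, factor: float) -> ResolvedScenario:
    """Multiply every group's production by ``factor`` (total scales exactly)."""
    if factor < 0:
        raise DataValidationError(f"scale factor must be >= 0, got {factor}")
    return replace(
        base,
        group_production={g: p * factor for g, p in base.group_production.items()},
    )


def zero_groups_with_compensation(
    base: ResolvedScenario,
    zero_groups: set[str],
    compensation_factor: float,
) -> ResolvedScenario:
    """Set the listed groups to zero and scale every other group."""
    unknown = sorted(set(zero_groups) - set(base.group_production))
    if unknown:
        raise UnknownVocabularyError(f"zero_groups references unknown group(s) {unknown}")
    if compensation_factor < 0:
        raise DataValidationError("compensation factor must be >= 0")
    production = {
        g: (0.0 if g in zero_groups else p * compensation_factor)
        for g, p in base.group_production.items()
    }
    return replace(base, group_production=production)


def remove_and_reallocate(
    base: ResolvedScenario,
    removed_group: str,
    recipients: Iterable[str] | None = None,
    group_table: pd.DataFrame | None = None,
) -> ResolvedScenario:
    """Zero one group and spread its mass proportionally over the recipients.

    Total biomass is conserved exactly.  When ``recipients`` is omitted the
    removed mass goes to every other plant group (requires ``group_table``
    with an ``origin`` column) — the construction used when sugar crops are
    taken out of the system.
    """
    if removed_group not in base.group_production:
        raise UnknownVocabularyError(f"unknown group '{removed_group}'")
    if recipients is None:
        if group_table is None:
            raise DataValidationError(
                "recipients not given and no group table to infer plant groups from"
            )
        recipients = [
            g for g in base.group_production
            if g != removed_group and group_table.loc[g, "origin"] == "plant"
        ]
    recipients = list(recipients)
    unknown = sorted(set(recipients) - set(base.group_production))
    if unknown:
        raise UnknownVocabularyError(f"recipients reference unknown group(s) {unknown}")
    if removed_group in recipients:
        raise DataValidationError(f"removed group '{removed_group}' cannot be a recipient")
    if not recipients:
        raise DataValidationError("recipients set is empty")

    removed_mass = base.group_production[removed_group]
    recipient_total = sum(base.group_production[g] for g in recipients)
    if removed_mass > 0 and recipient_total <= 0:
        raise DataValidationError(
            f"recipients {sorted(recipients)} have zero total production; "
            "cannot reallocate"
        )
    scale = 1.0 + (removed_mass / recipient_total if recipient_total > 0 else 0.0)
    production = dict(base.group_production)
    production[removed_group] = 0.0
    for g in recipients:
        production[g] = base.group_production[g] * scale
    return replace(base, group_production=production)


def biomass_preserving_compensation_factor(
    base: ResolvedScenario, zero_groups: set[str]
) -> float:
    """The compensation factor that would keep total biomass unchanged."""
    removed = sum(base.group_production[g] for g in zero_groups)
    remaining = base.total_biomass - removed
    if remaining <= 0:
        raise DataValidationError("no remaining production to compensate with")
    return 1.0 + removed / remaining


def detect_diet_mode(
    sc: ResolvedScenario,
    baseline_group_production: dict[str, float],
    groups: pd.DataFrame,
    config: ModelConfig = DEFAULT_CONFIG,
) -> str:
    """Classify a scenario as omnivore / vegetarian / vegan.

    An animal group counts as absent when its production falls below the
    configured fraction (default 1%) of its baseline.  Vegan: every animal
    group absent.  Vegetarian: all meat/fish groups absent while dairy or
    eggs (``vegetarian_ok`` groups) remain.  Otherwise omnivore.
    """
    thr = config.diet_mode_threshold
    animal = groups[groups["origin"] == "animal"]
    present: dict[str, bool] = {}
    for gid in animal.index:
        base = baseline_group_production.get(gid, 0.0)
        prod = sc.group_production.get(gid, 0.0)
        present[gid] = base > 0 and prod >= thr * base
    if not any(present.values()):
        return "vegan"
    meatlike = [g for g in animal.index if not animal.loc[g, "vegetarian_ok"]]
    if not any(present[g] for g in meatlike):
        return "vegetarian"
    return "omnivore"


def resolve_diet_mode(
    sc: ResolvedScenario,
    baseline_group_production: dict[str, float],
    groups: pd.DataFrame,
    config: ModelConfig = DEFAULT_CONFIG,
) -> ResolvedScenario:
    """Replace ``diet_mode='auto'`` with the detected mode."""
    if sc.diet_mode != "auto":
        return sc
    mode = detect_diet_mode(sc, baseline_group_production, groups, config)
    return replace(sc, diet_mode=mode)
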