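"""Demographically weighted intake targets, adequacy reporting, comparison.

A single "average global citizen" target per nutrient is the population-
share-weighted mean of the dietary reference values over every
(region × sex × age-group) stratum; reference values themselves vary only
by sex and age group, so regions contribute population weights only.
Lower and upper safe bounds are weighted the same way and are reported
only when every stratum carries them.  In vegetarian and vegan scenarios
the alternate (higher) iron and zinc targets replace the defaults before
weighting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .baseline import population_by_stratum
from .data_io import (
    DataValidationError,
    DELTA_REPORT_COLUMNS,
    NUTRIENT_REPORT_COLUMNS,
)
from .nutrition import NutrientSupply

logger = logging.getLogger(__name__)


def weighted_targets(
    drv: pd.DataFrame,
    demographics: pd.DataFrame,
    year: int,
    diet_mode: str = "omnivore",
) -> pd.DataFrame:
    """Demographically weighted target / lower / upper intake per nutrient.

    Returns a nutrient-indexed frame with columns ``target``, ``lower_safe``,
    ``upper_safe`` (NaN where any stratum lacks a bound) and ``unit``.
    """
    if diet_mode not in ("omnivore", "vegetarian", "vegan"):
        raise ValueError(f"diet_mode must be resolved, got '{diet_mode}'")
    strata_pop = population_by_stratum(demographics, year)
    total = strata_pop.sum()
    if total <= 0:
        raise DataValidationError(f"total population at {year} is not positive")
    # weights by (sex, age_group): regions only contribute population counts
    weights = strata_pop.groupby(level=["sex", "age_group"]).sum() / total
    assert abs(weights.sum() - 1.0) < 1e-12

    drv = drv.copy()
    alt_col = {"vegetarian": "alt_target_vegetarian", "vegan": "alt_target_vegan"}.get(diet_mode)
    if alt_col is not None:
        has_alt = drv[alt_col].notna()
        drv.loc[has_alt, "target"] = drv.loc[has_alt, alt_col]

    rows = []
    for nid, grp in drv.groupby("nutrient_id"):
        g = grp.set_index(["sex", "age_group"])
        missing = sorted(set(weights.index) - set(g.index))
        if missing:
            raise DataValidationError(
                f"DRV for nutrient '{nid}' missing stratum(s) {missing}"
            )
        g = g.reindex(weights.index)
        target = float((g["target"] * weights).sum())
        lower = (
            float((g["lower_safe"] * weights).sum())
            if g["lower_safe"].notna().all() else np.nan
        )
        upper = (
            float((g["upper_safe"] * weights).sum())
            if g["upper_safe"].notna().all() else np.nan
        )
        rows.append({
            "nutrient_id": nid, "target": target, "lower_safe": lower,
            "upper_safe": upper, "unit": g["unit"].iloc[0],
        })
    return pd.DataFrame(rows).set_index("nutrient_id").sort_index()


def adequacy_report(
    supply: NutrientSupply,
    targets: pd.DataFrame,
    material_threshold_pct: float = 5.0,
) -> pd.DataFrame:
    """Per-nutrient gap/excess report against the weighted targets.

    gap_pct = max(0, 100·(target − supply)/target); excess_pct =
    max(0, 100·(supply − upper)/upper) where an upper bound exists (NaN
    otherwise).  Every nutrient appears — filtering small gaps is a display
    concern; the ``material`` flag marks gaps above the threshold.
    """
    rows = []
    for nid in sorted(supply.supply.index):
        s = float(supply.supply[nid])
        if nid not in targets.index:
            logger.warning("nutrient '%s' has supply but no target; row emitted without gap", nid)
            rows.append({
                "nutrient_id": nid, "unit": "", "supply": s, "target": np.nan,
                "lower_safe": np.nan, "upper_safe": np.nan, "pct_of_target": np.nan,
                "gap_pct": np.nan, "excess_pct": np.nan, "material": False,
            })
            continue
        t = float(targets.loc[nid, "target"])
        lower = float(targets.loc[nid, "lower_safe"])
        upper = float(targets.loc[nid, "upper_safe"])
        gap = max(0.0, 100.0 * (t - s) / t)
        excess = max(0.0, 100.0 * (s - upper) / upper) if np.isfinite(upper) else np.nan
        rows.append({
            "nutrient_id": nid, "unit": targets.loc[nid, "unit"], "supply": s,
            "target": t, "lower_safe": lower, "upper_safe": upper,
            "pct_of_target": 100.0 * s / t, "gap_pct": gap, "excess_pct": excess,
            "material": bool(gap > material_threshold_pct),
        })
    return pd.DataFrame(rows, columns=NUTRIENT_REPORT_COLUMNS).reset_index(drop=True)


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Display form: percentages rounded to integers, immaterial gaps blanked."""
    disp = report.copy()
    for col in ("pct_of_target", "gap_pct", "excess_pct"):
        disp[col] = disp[col].round(0)
    disp.loc[~disp["material"], "gap_pct"] = np.nan
    return disp


def compare_scenarios(
    report_a: pd.DataFrame,
    mass_a: pd.DataFrame,
    report_b: pd.DataFrame,
    mass_b: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Δ between two runs: per-nutrient supply/gap deltas, per-group biomass deltas.

    The nutrient frames must cover the same nutrient vocabulary.
    """
    set_a, set_b = set(report_a["nutrient_id"]), set(report_b["nutrient_id"])
    if set_a != set_b:
        raise DataValidationError(
            "nutrient sets differ between runs: "
            f"only in a: {sorted(set_a - set_b)}, only in b: {sorted(set_b - set_a)}"
        )
    a = report_a.set_index("nutrient_id").sort_index()
    b = report_b.set_index("nutrient_id").sort_index()
    nutrients = pd.DataFrame({
        "nutrient_id": a.index,
        "supply_a": a["supply"].to_numpy(),
        "supply_b": b["supply"].to_numpy(),
        "delta_supply": (b["supply"] - a["supply"]).to_numpy(),
        "delta_gap_pct": (b["gap_pct"] - a["gap_pct"]).to_numpy(),
    }, columns=DELTA_REPORT_COLUMNS)

    ga = mass_a.groupby("group_id")["production_t"].sum()
    gb = mass_b.groupby("group_id")["production_t"].sum()
    all_groups = sorted(set(ga.index) | set(gb.index))
    groups = pd.DataFrame({
        "group_id": all_groups,
        "production_a_t": [float(ga.get(g, 0.0)) for g in all_groups],
        "production_b_t": [float(gb.get(g, 0.0)) for g in all_groups],
    })
    groups["delta_production_t"] = groups["production_b_t"] - groups["production_a_t"]
    return {"nutrients": nutrients, "groups": groups}
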