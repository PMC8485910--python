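"""Baseline-year derivation from the multi-year commodity balance table.

The baseline year (2018 for the shipped study conditions) lies one year
beyond the balance-sheet history, so per-item production is extrapolated by
a weighted linear fit of the historical series.  All proportions the
scenario engine needs — item shares within each food group, feed / supply
chain loss / nonfood fractions of farm-gate production, and feed-to-animal
group attribution — are derived from the pooled (summed) history, which is
robust to individual years with zero production.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, ModelConfig
from .data_io import DataValidationError, Dataset

logger = logging.getLogger(__name__)


class SingleYearHistoryError(DataValidationError):
    """Raised when an item has only one history year and no carry-forward flag."""


@dataclass
class BaselineShares:
    """Baseline production and every proportion derived from the balance table.

    ``feed_attribution`` maps ``(feed item_id, animal group_id)`` to the
    baseline tonnage of that item fed to that animal group; dividing by the
    animal group's baseline production gives tons of feed per ton of product.
    """

    item_share: dict[str, float]
    feed_fraction: dict[str, float]
    loss_fraction: dict[str, float]
    nonfood_fraction: dict[str, float]
    baseline_production: dict[str, float]
    baseline_population: float
    baseline_year: int
    item_group: dict[str, str] = field(default_factory=dict)
    feed_attribution: dict[tuple[str, str], float] = field(default_factory=dict)

    def group_production(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for item, prod in self.baseline_production.items():
            out[self.item_group[item]] = out.get(self.item_group[item], 0.0) + prod
        return out


def _interpolation_weights(n_years: int, config: ModelConfig) -> np.ndarray:
    scheme = config.interpolation.weights
    if scheme == "uniform":
        return np.ones(n_years)
    if scheme == "linear":
        if n_years == 1:
            return np.ones(1)
        return 1.0 + np.arange(n_years) / (n_years - 1)
    if scheme == "custom":
        w = np.asarray(config.interpolation.custom_weights, dtype=float)
        if w.shape != (n_years,) or (w <= 0).any():
            raise DataValidationError(
                f"custom interpolation weights must be {n_years} positive values"
            )
        return w
    raise ValueError(f"unknown weighting scheme '{scheme}'")


def interpolate_production(
    history: pd.DataFrame,
    target_year: int,
    config: ModelConfig = DEFAULT_CONFIG,
    allow_constant_carry_forward: bool = False,
) -> dict[str, float]:
    """Extrapolate per-item production to ``target_year``.

    ``history`` is a balance-style frame with at least ``item_id``, ``year``
    and ``production_t``.  A weighted least-squares line is fitted per item
    (weights per the configured scheme, oldest year first) and evaluated at
    the target year; negative extrapolations clamp to zero with a warning.
    """
    out: dict[str, float] = {}
    for item_id, grp in history.groupby("item_id"):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy(dtype=float)
        prod = grp["production_t"].to_numpy(dtype=float)
        if len(years) < 2:
            if allow_constant_carry_forward:
                out[item_id] = float(prod[-1])
                continue
            raise SingleYearHistoryError(
                f"item '{item_id}' has a single history year; pass "
                "allow_constant_carry_forward=True to carry it forward"
            )
        if target_year <= years.max():
            raise DataValidationError(
                f"target_year {target_year} must exceed the last history year "
                f"{int(years.max())}"
            )
        w = _interpolation_weights(len(years), config)
        # weighted 2x2 normal equations on centred years (conditioning)
        x = years - years.mean()
        sw, swx = w.sum(), (w * x).sum()
        swxx, swy, swxy = (w * x * x).sum(), (w * prod).sum(), (w * x * prod).sum()
        a, b = np.linalg.solve([[sw, swx], [swx, swxx]], [swy, swxy])
        value = a + b * (target_year - years.mean())
        if value < 0:
            logger.warning(
                "extrapolated production for item '%s' at %d is negative (%.3f t); "
                "clamping to 0", item_id, target_year, value,
            )
            value = 0.0
        out[item_id] = float(value)
    return out


def population_by_stratum(demographics: pd.DataFrame, year: int) -> pd.Series:
    """Population per (region, sex, age_group) stratum at ``year``.

    Years absent from the table are linearly interpolated per stratum
    between the nearest tabulated years; years outside the tabulated span
    raise, since silent extrapolation of demographics is never wanted.
    """
    years = sorted(demographics["year"].unique())
    pivot = demographics.pivot_table(
        index=["region_id", "sex", "age_group"], columns="year",
        values="population", aggfunc="sum",
    )
    if year in years:
        return pivot[year]
    lo = [y for y in years if y < year]
    hi = [y for y in years if y > year]
    if not lo or not hi:
        raise DataValidationError(
            f"demographics: year {year} outside tabulated span {years[0]}–{years[-1]}"
        )
    y0, y1 = lo[-1], hi[0]
    t = (year - y0) / (y1 - y0)
    return pivot[y0] * (1 - t) + pivot[y1] * t


def total_population(demographics: pd.DataFrame, year: int) -> float:
    return float(population_by_stratum(demographics, year).sum())


def derive_shares(
    table: pd.DataFrame,
    demographics: pd.DataFrame,
    baseline_year: int,
    item_group: dict[str, str] | None = None,
    config: ModelConfig = DEFAULT_CONFIG,
    allow_constant_carry_forward: bool = False,
) -> BaselineShares:
    """Derive baseline production and all baseline proportions.

    Item shares within a group and per-item utilization fractions come from
    masses pooled (summed) across every history year; baseline production
    comes from :func:`interpolate_production` at ``baseline_year``.
    """
    if table.empty:
        raise DataValidationError("balance table is empty")
    pooled = table.groupby("item_id").agg(
        group_id=("group_id", "first"),
        production_t=("production_t", "sum"),
        feed_t=("feed_t", "sum"),
        supply_chain_loss_t=("supply_chain_loss_t", "sum"),
        nonfood_t=("nonfood_t", "sum"),
    )
    group_totals = pooled.groupby("group_id")["production_t"].sum()
    zero_groups = sorted(group_totals.index[group_totals <= 0])
    if zero_groups:
        raise DataValidationError(
            f"group(s) {zero_groups} have zero pooled production; item shares undefined"
        )

    item_share: dict[str, float] = {}
    feed_fraction: dict[str, float] = {}
    loss_fraction: dict[str, float] = {}
    nonfood_fraction: dict[str, float] = {}
    for item_id, row in pooled.iterrows():
        item_share[item_id] = float(row["production_t"] / group_totals[row["group_id"]])
        if row["production_t"] > 0:
            feed_fraction[item_id] = float(row["feed_t"] / row["production_t"])
            loss_fraction[item_id] = float(row["supply_chain_loss_t"] / row["production_t"])
            nonfood_fraction[item_id] = float(row["nonfood_t"] / row["production_t"])
        else:
            feed_fraction[item_id] = loss_fraction[item_id] = nonfood_fraction[item_id] = 0.0

    baseline_production = interpolate_production(
        table, baseline_year, config=config,
        allow_constant_carry_forward=allow_constant_carry_forward,
    )
    return BaselineShares(
        item_share=item_share,
        feed_fraction=feed_fraction,
        loss_fraction=loss_fraction,
        nonfood_fraction=nonfood_fraction,
        baseline_production=baseline_production,
        baseline_population=total_population(demographics, baseline_year),
        baseline_year=baseline_year,
        item_group=pooled["group_id"].to_dict(),
    )


def derive_feed_attribution(
    shares: BaselineShares,
    animal_production: dict[str, float],
    attribution_input: pd.DataFrame | None = None,
) -> dict[tuple[str, str], float]:
    """Attribute each feed item's baseline feed tonnage across animal groups.

    With an explicit table (columns ``feed_item_id``, ``animal_group_id``,
    ``tons``) the rows are normalized so each item's attributed tonnage sums
    to its baseline feed tonnage; rows exceeding that tonnage in total are
    an error.  Without one, tonnage is split proportionally to the animal
    groups' baseline production.
    """
    baseline_feed = {
        item: shares.feed_fraction[item] * shares.baseline_production.get(item, 0.0)
        for item in shares.feed_fraction
    }
    fed_items = {i for i, t in baseline_feed.items() if t > 0}
    attribution: dict[tuple[str, str], float] = {}

    if attribution_input is not None:
        for col in ("feed_item_id", "animal_group_id", "tons"):
            if col not in attribution_input.columns:
                raise DataValidationError(f"feed attribution table: missing column '{col}'")
        neg = attribution_input[attribution_input["tons"] < 0]
        if not neg.empty:
            r = neg.iloc[0]
            raise DataValidationError(
                f"feed attribution: negative tons for (feed_item_id={r.feed_item_id}, "
                f"animal_group_id={r.animal_group_id})"
            )
        unknown = sorted(set(attribution_input["animal_group_id"]) - set(animal_production))
        if unknown:
            raise DataValidationError(f"feed attribution: unknown animal group(s) {unknown}")
        by_item = attribution_input.groupby("feed_item_id")
        for item, grp in by_item:
            total = float(grp["tons"].sum())
            target = baseline_feed.get(item, 0.0)
            if total > target * (1 + 1e-9):
                raise DataValidationError(
                    f"feed attribution: rows for item '{item}' total {total} t, "
                    f"exceeding its baseline feed tonnage {target} t"
                )
            if total <= 0:
                continue
            # normalize so the item's attributed tonnage sums to its baseline feed
            for _, r in grp.iterrows():
                attribution[(item, r["animal_group_id"])] = (
                    float(r["tons"]) / total * target
                )
            fed_items.discard(item)

    if fed_items:
        animal_total = sum(animal_production.values())
        if animal_total <= 0:
            raise DataValidationError(
                f"feed item(s) {sorted(fed_items)} have baseline feed use but no "
                "animal group has positive baseline production to attribute it to"
            )
        for item in fed_items:
            for group, prod in animal_production.items():
                if prod > 0:
                    attribution[(item, group)] = baseline_feed[item] * prod / animal_total
    return attribution
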