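"""Synthetic miniature worlds and an independent brute-force oracle.

Three dataset shapes are generated, all self-consistent and loadable by
:func:`delta.data_io.load_dataset`:

``analytic``
    A fixed, seed-free world of 2 groups × 3 items with round-number
    masses whose every pipeline output has a documented closed form (see
    docs/methods.md).
``mini``
    A small randomized world (3 groups, 8 items, 2 regions) for fast
    property tests.
``paper``-shaped
    The full study geometry — 15 food groups (6 animal-sourced, 9
    plant-sourced), 121 commodities, 5 regions, 21 age groups, 2 sexes,
    20 balance-sheet years — with randomized but invariant-respecting
    values.  Only the shape matches the real datasets, never their values.

The oracle re-derives every pipeline output by plain nested-loop
arithmetic over dicts read with the stdlib csv module; it shares no code
with the pipeline, so agreement between the two is a genuine dual-route
check.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import DataValidationError
from .massflow import InfeasibleScenarioError

NUTRIENT_COLUMNS = [
    "energy[kcal]", "protein[g]", "fat[g]", "calcium[mg]", "iron[mg]",
    "zinc[mg]", "vitamin_e[mg]", "lysine[g]",
]

PAPER_GROUPS = [
    # (group_id, origin, vegetarian_ok) — 6 animal-sourced, 9 plant-sourced
    ("ruminant_meat", "animal", False),
    ("poultry_meat", "animal", False),
    ("other_meat", "animal", False),
    ("fish_seafood", "animal", False),
    ("eggs", "animal", True),
    ("dairy", "animal", True),
    ("cereals", "plant", False),
    ("fruit", "plant", False),
    ("nuts", "plant", False),
    ("oilcrops", "plant", False),
    ("pulses", "plant", False),
    ("starchy_roots", "plant", False),
    ("sugar", "plant", False),
    ("vegetables", "plant", False),
    ("other_plants", "plant", False),
]


@dataclass
class WorldSpec:
    """Geometry and seed of a generated world."""

    seed: int = 0
    n_regions: int = 2
    n_groups: int = 3
    n_items: int = 8
    n_age_groups: int = 3
    year_range: tuple[int, int] = (2014, 2017)
    shape: str = "mini"

    def __post_init__(self) -> None:
        if self.shape == "paper":
            self.n_regions, self.n_groups = 5, 15
            self.n_items, self.n_age_groups = 121, 21
            self.year_range = (1998, 2017)
        if self.n_items < self.n_groups:
            raise DataValidationError(
                f"n_items ({self.n_items}) must be >= n_groups ({self.n_groups})"
            )


def _write_csv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


# ---------------------------------------------------------------------------
# Analytic world
# ---------------------------------------------------------------------------


def make_analytic_world(out_dir: Path | str) -> Path:
    """Write the fixed 2-group / 3-item world with closed-form outputs.

    Baseline year 2018 (constant 2016–2017 history), population 10 000.
    The hand-derived cascade (documented in docs/methods.md):
    wheat consumed 526.5 t → 144.246575... g/day; apple 324 t →
    88.767123... g/day; milk 360 t → 98.630136... g/day.
    """
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    _write_csv(d / "groups.csv", ["group_id", "origin", "vegetarian_ok"], [
        ["plants", "plant", False],
        ["dairy", "animal", True],
    ])
    _write_csv(d / "regions.csv", ["region_id"], [["north"], ["south"]])
    balance_rows = []
    for year in (2016, 2017):
        balance_rows += [
            ["wheat", "plants", year, 1000, 200, 100, 50],
            ["apple", "plants", year, 500, 0, 50, 0],
            ["milk", "dairy", year, 400, 0, 0, 0],
        ]
    _write_csv(
        d / "balance.csv",
        ["item_id", "group_id", "year", "production_t", "feed_t",
         "supply_chain_loss_t", "nonfood_t"],
        balance_rows,
    )
    _write_csv(
        d / "items.csv",
        ["item_id", "group_id", "origin", "inedible_fraction",
         *NUTRIENT_COLUMNS[:2], "calcium[mg]", "iron[mg]", "lysine[g]",
         "dig:protein", "dig:lysine"],
        [
            ["wheat", "plants", "plant", 0.1, 340, 12, 30, 3.5, 0.3, 0.8, 0.75],
            ["apple", "plants", "plant", 0.2, 50, 0.3, 6, 0.1, 0.02, 0.5, 0.5],
            ["milk", "dairy", "animal", 0.0, 65, 3.4, 120, 0.03, 0.28, 0.95, 0.95],
        ],
    )
    _write_csv(d / "waste.csv", ["region_id", "group_id", "waste_fraction"], [
        ["north", "plants", 0.15],
        ["south", "plants", 0.05],
        ["north", "dairy", 0.1],
        ["south", "dairy", 0.1],
    ])
    demo_rows = []
    for year, cell in ((2018, 1250), (2030, 1500)):
        for region in ("north", "south"):
            for sex in ("F", "M"):
                for age in ("child", "adult"):
                    demo_rows.append([region, sex, age, year, cell])
    _write_csv(
        d / "demographics.csv",
        ["region_id", "sex", "age_group", "year", "population"],
        demo_rows,
    )
    drv_rows = []
    # nutrient: {(age): (target, lower, upper, alt_veg_mult, alt_vegan_mult)}
    spec = {
        "energy": ("kcal", {"child": (1800, "", 2700), "adult": (2200, "", 3300)}, None),
        "protein": ("g", {"child": (40, 30, ""), "adult": (50, 40, "")}, None),
        "calcium": ("mg", {"child": (1000, 700, 2500), "adult": (1000, 700, 2500)}, None),
        "iron": ("mg", {"child": (8, "", ""), "adult": (14, "", "")}, (1.5, 1.8)),
        "lysine": ("g", {"child": (2.0, "", ""), "adult": (2.0, "", "")}, None),
    }
    for nid, (unit, by_age, alts) in spec.items():
        for sex in ("F", "M"):
            for age, (target, lower, upper) in by_age.items():
                veg = target * alts[0] if alts else ""
                vegan = target * alts[1] if alts else ""
                drv_rows.append([nid, sex, age, target, lower, upper, unit, veg, vegan])
    _write_csv(
        d / "drv.csv",
        ["nutrient_id", "sex", "age_group", "target", "lower_safe", "upper_safe",
         "unit", "alt_target_vegetarian", "alt_target_vegan"],
        drv_rows,
    )
    return d


#: hand-derived cascade values for the analytic world's 2018 baseline
ANALYTIC_EXPECTED = {
    "population": 10_000.0,
    "consumed_edible_t": {"wheat": 526.5, "apple": 324.0, "milk": 360.0},
    "per_capita_g_day": {
        "wheat": 526.5e6 / 10_000 / 365,
        "apple": 324.0e6 / 10_000 / 365,
        "milk": 360.0e6 / 10_000 / 365,
    },
}


# ---------------------------------------------------------------------------
# Randomized worlds
# ---------------------------------------------------------------------------


def make_world(spec: WorldSpec, out_dir: Path | str) -> Path:
    """Write a randomized, invariant-respecting world for ``spec``.

    Masses are log-uniform over [1e3, 1e7] t; utilization and waste
    fractions are Beta-distributed and rescaled so feed+loss+nonfood never
    exceeds 90% of production.  Deterministic given ``spec.seed``.
    """
    if spec.shape == "analytic":
        return make_analytic_world(out_dir)
    rng = np.random.default_rng(spec.seed)
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)

    if spec.shape == "paper":
        groups = list(PAPER_GROUPS)
    else:
        groups = []
        n_animal = max(1, spec.n_groups // 3) if spec.n_groups > 1 else 0
        for i in range(spec.n_groups):
            if i < n_animal:
                # first animal group is meat-like so baselines read as omnivore
                groups.append((f"g{i:02d}_animal", "animal", i % 2 == 1))
            else:
                groups.append((f"g{i:02d}_plant", "plant", False))
    group_ids = [g for g, _, _ in groups]
    origin_of = {g: o for g, o, _ in groups}
    _write_csv(d / "groups.csv", ["group_id", "origin", "vegetarian_ok"],
               [[g, o, v] for g, o, v in groups])

    regions = [f"r{i:02d}" for i in range(spec.n_regions)]
    _write_csv(d / "regions.csv", ["region_id"], [[r] for r in regions])

    # each group gets one item, remainder round-robin over a shuffled order
    item_group: dict[str, str] = {}
    order = list(group_ids)
    rng.shuffle(order)
    for i in range(spec.n_items):
        item_group[f"i{i:03d}"] = order[i % len(order)]
    items = sorted(item_group)

    years = list(range(spec.year_range[0], spec.year_range[1] + 1))
    base = 10 ** rng.uniform(3, 7, size=len(items))
    trend = rng.uniform(-0.01, 0.03, size=len(items))
    feed_frac = np.where(
        [origin_of[item_group[i]] == "plant" for i in items],
        rng.beta(2, 8, size=len(items)) * (rng.random(len(items)) < 0.6),
        0.0,
    )
    has_animal = any(o == "animal" for o in origin_of.values())
    if not has_animal:
        feed_frac = np.zeros(len(items))
    loss_frac = rng.beta(2, 12, size=len(items))
    nonfood_frac = rng.beta(2, 12, size=len(items)) * (rng.random(len(items)) < 0.5)
    total = feed_frac + loss_frac + nonfood_frac
    scale = np.where(total > 0.9, 0.9 / np.maximum(total, 1e-12), 1.0)
    feed_frac, loss_frac, nonfood_frac = feed_frac * scale, loss_frac * scale, nonfood_frac * scale

    balance_rows = []
    for j, item in enumerate(items):
        for year in years:
            prod = base[j] * (1 + trend[j]) ** (year - years[0]) * rng.lognormal(0, 0.05)
            balance_rows.append([
                item, item_group[item], year, prod,
                feed_frac[j] * prod, loss_frac[j] * prod, nonfood_frac[j] * prod,
            ])
    _write_csv(
        d / "balance.csv",
        ["item_id", "group_id", "year", "production_t", "feed_t",
         "supply_chain_loss_t", "nonfood_t"],
        balance_rows,
    )

    item_rows = []
    for j, item in enumerate(items):
        inedible = min(float(rng.beta(2, 8)), 0.8)
        protein = rng.uniform(0.2, 25)
        row = [
            item, item_group[item], origin_of[item_group[item]], inedible,
            rng.uniform(30, 600),          # energy
            protein,                        # protein
            rng.uniform(0.1, 30),           # fat
            rng.uniform(2, 300),            # calcium
            rng.uniform(0.02, 8),           # iron
            rng.uniform(0.05, 6),           # zinc
            rng.uniform(0.01, 5),           # vitamin E
            protein * rng.uniform(0.02, 0.08),  # lysine
            rng.uniform(0.3, 1.0),          # dig:protein
            rng.uniform(0.3, 1.0),          # dig:lysine
        ]
        item_rows.append(row)
    _write_csv(
        d / "items.csv",
        ["item_id", "group_id", "origin", "inedible_fraction", *NUTRIENT_COLUMNS,
         "dig:protein", "dig:lysine"],
        item_rows,
    )

    waste_rows = [
        [r, g, float(rng.beta(2, 10))] for r in regions for g in group_ids
    ]
    _write_csv(d / "waste.csv", ["region_id", "group_id", "waste_fraction"], waste_rows)

    baseline_year = years[-1] + 1
    ages = [f"a{i:02d}" for i in range(spec.n_age_groups)]
    demo_rows = []
    base_pop = rng.uniform(1e4, 1e6, size=(len(regions), 2, len(ages)))
    for year, factor in ((baseline_year, 1.0), (baseline_year + 12, 1.12), (baseline_year + 32, 1.28)):
        for ri, region in enumerate(regions):
            for si, sex in enumerate(("F", "M")):
                for ai, age in enumerate(ages):
                    jitter = rng.uniform(0.95, 1.05) if factor != 1.0 else 1.0
                    demo_rows.append([region, sex, age, year, base_pop[ri, si, ai] * factor * jitter])
    _write_csv(
        d / "demographics.csv",
        ["region_id", "sex", "age_group", "year", "population"],
        demo_rows,
    )

    nutrient_base = {
        "energy": ("kcal", 2100), "protein": ("g", 50), "fat": ("g", 65),
        "calcium": ("mg", 1000), "iron": ("mg", 12), "zinc": ("mg", 10),
        "vitamin_e": ("mg", 12), "lysine": ("g", 2.1),
    }
    drv_rows = []
    for nid, (unit, base_target) in nutrient_base.items():
        has_lower = rng.random() < 0.6
        has_upper = rng.random() < 0.6
        stratum_mult = rng.uniform(0.7, 1.3, size=(2, len(ages)))
        for si, sex in enumerate(("F", "M")):
            for ai, age in enumerate(ages):
                target = base_target * stratum_mult[si, ai]
                lower = target * rng.uniform(0.6, 0.8) if has_lower else ""
                upper = target * rng.uniform(1.5, 2.5) if has_upper else ""
                alt_veg = target * 1.5 if nid in ("iron", "zinc") else ""
                alt_vegan = target * 1.8 if nid in ("iron", "zinc") else ""
                drv_rows.append([nid, sex, age, target, lower, upper, unit, alt_veg, alt_vegan])
    _write_csv(
        d / "drv.csv",
        ["nutrient_id", "sex", "age_group", "target", "lower_safe", "upper_safe",
         "unit", "alt_target_vegetarian", "alt_target_vegan"],
        drv_rows,
    )
    return d


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def _read_rows(path: Path) -> list[dict[str, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def _f(value: str) -> float:
    return float(value) if value not in ("", None) else math.nan


def oracle_evaluate(data_dir: Path | str, scenario: dict | None = None) -> dict:
    """Recompute the entire cascade and reports by naive nested iteration.

    ``scenario`` is a plain dict with the scenario-file vocabulary
    (``groups``, ``zero_groups``/``compensation_factor``, ``remove_group``/
    ``recipients``, waste multipliers, ``population_year``, ``nonfood_mode``,
    ``diet_mode``).  Returns plain dicts keyed by item / nutrient id.
    """
    sc = dict(scenario or {})
    d = Path(data_dir)
    groups = {r["group_id"]: r for r in _read_rows(d / "groups.csv")}
    balance = _read_rows(d / "balance.csv")
    item_rows = _read_rows(d / "items.csv")
    waste_rows = _read_rows(d / "waste.csv")
    demo_rows = _read_rows(d / "demographics.csv")
    drv_rows = _read_rows(d / "drv.csv")

    # --- baseline proportions from pooled history ------------------------
    pooled: dict[str, dict[str, float]] = {}
    item_group: dict[str, str] = {}
    series: dict[str, dict[int, float]] = {}
    for r in balance:
        item = r["item_id"]
        item_group[item] = r["group_id"]
        p = pooled.setdefault(item, {"production": 0.0, "feed": 0.0, "loss": 0.0, "nonfood": 0.0})
        p["production"] += float(r["production_t"])
        p["feed"] += float(r["feed_t"])
        p["loss"] += float(r["supply_chain_loss_t"])
        p["nonfood"] += float(r["nonfood_t"])
        series.setdefault(item, {})[int(r["year"])] = (
            series.get(item, {}).get(int(r["year"]), 0.0) + float(r["production_t"])
        )
    group_pool: dict[str, float] = {}
    for item, p in pooled.items():
        group_pool[item_group[item]] = group_pool.get(item_group[item], 0.0) + p["production"]
    share = {i: pooled[i]["production"] / group_pool[item_group[i]] for i in pooled}
    frac = {
        i: {
            k: (pooled[i][k] / pooled[i]["production"] if pooled[i]["production"] > 0 else 0.0)
            for k in ("feed", "loss", "nonfood")
        }
        for i in pooled
    }

    # --- baseline-year production: weighted LSQ line, weights 1 -> 2 ------
    last_year = max(y for s in series.values() for y in s)
    baseline_year = last_year + 1
    baseline_prod: dict[str, float] = {}
    for item, s in series.items():
        ys = sorted(s)
        n = len(ys)
        ws = [1.0 + k / (n - 1) for k in range(n)] if n > 1 else [1.0]
        xbar = sum(ys) / n
        sw = sum(ws)
        swx = sum(w * (y - xbar) for w, y in zip(ws, ys))
        swxx = sum(w * (y - xbar) ** 2 for w, y in zip(ws, ys))
        swy = sum(w * s[y] for w, y in zip(ws, ys))
        swxy = sum(w * (y - xbar) * s[y] for w, y in zip(ws, ys))
        det = sw * swxx - swx * swx
        a = (swy * swxx - swx * swxy) / det
        b = (sw * swxy - swx * swy) / det
        baseline_prod[item] = max(0.0, a + b * (baseline_year - xbar))
    group_base = {}
    for item, prod in baseline_prod.items():
        group_base[item_group[item]] = group_base.get(item_group[item], 0.0) + prod

    # --- feed attribution (fallback: proportional to animal production) ---
    animal_groups = [g for g, r in groups.items() if r["origin"] == "animal"]
    animal_base_total = sum(group_base.get(g, 0.0) for g in animal_groups)
    attribution: dict[tuple[str, str], float] = {}
    for item in pooled:
        base_feed = frac[item]["feed"] * baseline_prod[item]
        if base_feed <= 0:
            continue
        if animal_base_total <= 0:
            raise DataValidationError(
                f"feed item '{item}' has no animal group to attribute feed to"
            )
        for g in animal_groups:
            if group_base.get(g, 0.0) > 0:
                attribution[(item, g)] = base_feed * group_base[g] / animal_base_total

    # --- scenario resolution ---------------------------------------------
    production = dict(group_base)
    for gid, change in (sc.get("groups") or {}).items():
        if gid not in production:
            raise DataValidationError(f"unknown group '{gid}' in scenario")
        if isinstance(change, dict) and "tons" in change:
            production[gid] = float(change["tons"])
        elif isinstance(change, dict) and "multiplier" in change:
            production[gid] = production[gid] * float(change["multiplier"])
        else:
            production[gid] = production[gid] * float(change)
    if sc.get("zero_groups"):
        comp = float(sc.get("compensation_factor", 1.0))
        production = {
            g: (0.0 if g in sc["zero_groups"] else p * comp)
            for g, p in production.items()
        }
    if sc.get("remove_group"):
        removed = sc["remove_group"]
        recipients = sc.get("recipients") or [
            g for g in production
            if g != removed and groups[g]["origin"] == "plant"
        ]
        removed_mass = production[removed]
        rec_total = sum(production[g] for g in recipients)
        if removed_mass > 0 and rec_total <= 0:
            raise DataValidationError("recipients have zero total production")
        k = 1.0 + (removed_mass / rec_total if rec_total > 0 else 0.0)
        new = dict(production)
        new[removed] = 0.0
        for g in recipients:
            new[g] = production[g] * k
        production = new

    # --- population -------------------------------------------------------
    pop_year = int(sc.get("population_year") or baseline_year)

    def population_at(year: int) -> dict[tuple[str, str, str], float]:
        by_year: dict[int, dict[tuple[str, str, str], float]] = {}
        for r in demo_rows:
            key = (r["region_id"], r["sex"], r["age_group"])
            by_year.setdefault(int(r["year"]), {})[key] = float(r["population"])
        years = sorted(by_year)
        if year in by_year:
            return by_year[year]
        lo = [y for y in years if y < year]
        hi = [y for y in years if y > year]
        if not lo or not hi:
            raise DataValidationError(f"year {year} outside demographic span")
        y0, y1 = lo[-1], hi[0]
        t = (year - y0) / (y1 - y0)
        return {
            k: by_year[y0][k] * (1 - t) + by_year[y1][k] * t for k in by_year[y0]
        }

    strata = population_at(pop_year)
    population = sum(strata.values())
    base_population = sum(population_at(baseline_year).values())

    # --- diet mode ---------------------------------------------------------
    diet_mode = sc.get("diet_mode", "auto")
    if diet_mode == "auto":
        present = {}
        for g in animal_groups:
            base = group_base.get(g, 0.0)
            present[g] = base > 0 and production.get(g, 0.0) >= 0.01 * base
        if not any(present.values()):
            diet_mode = "vegan"
        elif not any(
            present[g] for g in animal_groups if groups[g]["vegetarian_ok"] not in ("True", "true", True)
        ):
            diet_mode = "vegetarian"
        else:
            diet_mode = "omnivore"

    # --- in-home waste collapse (population weighted) ----------------------
    region_pop: dict[str, float] = {}
    for (region, _, _), p in strata.items():
        region_pop[region] = region_pop.get(region, 0.0) + p
    group_waste: dict[str, float] = {}
    for gid in groups:
        num = den = 0.0
        for r in waste_rows:
            if r["group_id"] == gid:
                num += float(r["waste_fraction"]) * region_pop[r["region_id"]]
                den += region_pop[r["region_id"]]
        if den > 0:
            group_waste[gid] = num / den

    # --- cascade ------------------------------------------------------------
    scm = float(sc.get("supply_chain_waste_multiplier", 1.0))
    ihm = float(sc.get("in_home_waste_multiplier", 1.0))
    nonfood_mode = sc.get("nonfood_mode", "per_capita_constant")
    profiles = {r["item_id"]: r for r in item_rows}

    result_items: dict[str, dict[str, float]] = {}
    for item in sorted(pooled):
        gid = item_group[item]
        prod = production.get(gid, 0.0) * share[item]
        feed = 0.0
        for (fi, g), tons in attribution.items():
            if fi == item and group_base.get(g, 0.0) > 0:
                feed += tons * (production.get(g, 0.0) / group_base[g])
        if feed > prod * (1 + 1e-9):
            raise InfeasibleScenarioError(
                f"feed demand for '{item}' exceeds its production"
            )
        loss = frac[item]["loss"] * prod * scm
        if nonfood_mode == "per_capita_constant":
            nonfood = frac[item]["nonfood"] * baseline_prod[item] * population / base_population
        else:
            nonfood = frac[item]["nonfood"] * prod
        available = prod - feed - loss - nonfood
        if available < -1e-9 * max(prod, 1.0):
            raise InfeasibleScenarioError(
                f"negative availability for '{item}' after feed/loss/nonfood"
            )
        available = max(available, 0.0)
        inedible_fraction = float(profiles[item]["inedible_fraction"])
        inedible = available * inedible_fraction
        edible = available - inedible
        wf = group_waste.get(gid, 0.0) * ihm
        if wf > 1:
            raise InfeasibleScenarioError(f"in-home waste fraction > 1 for '{item}'")
        in_home = edible * wf
        consumed = edible - in_home
        result_items[item] = {
            "production_t": prod, "feed_t": feed, "supply_chain_loss_t": loss,
            "nonfood_t": nonfood, "inedible_t": inedible, "in_home_waste_t": in_home,
            "consumed_edible_t": consumed,
            "per_capita_g_day": consumed * 1e6 / population / 365.0,
        }

    # --- nutrients -----------------------------------------------------------
    nutrient_units: dict[str, str] = {}
    for col in item_rows[0]:
        if "[" in col and col.endswith("]"):
            nid, unit = col[:-1].split("[")
            nutrient_units[nid] = unit

    def nutrients_of(alloc: dict[str, float]) -> dict[str, float]:
        out = {n: 0.0 for n in nutrient_units}
        for item, g_day in alloc.items():
            row = profiles[item]
            for nid, unit in nutrient_units.items():
                dens = float(row[f"{nid}[{unit}]"])
                dig_col = f"dig:{nid}"
                dig = float(row[dig_col]) if dig_col in row and row[dig_col] != "" else 1.0
                out[nid] += g_day / 100.0 * dens * dig
        return out

    supply = nutrients_of({i: r["per_capita_g_day"] for i, r in result_items.items()})
    wasted_alloc = {
        i: (
            r["supply_chain_loss_t"] * (1 - float(profiles[i]["inedible_fraction"]))
            + r["in_home_waste_t"]
        ) * 1e6 / population / 365.0
        for i, r in result_items.items()
    }
    wasted = nutrients_of(wasted_alloc)

    # --- weighted targets -----------------------------------------------------
    sexage_pop: dict[tuple[str, str], float] = {}
    for (region, sex, age), p in strata.items():
        sexage_pop[(sex, age)] = sexage_pop.get((sex, age), 0.0) + p
    targets: dict[str, float] = {}
    lowers: dict[str, float] = {}
    uppers: dict[str, float] = {}
    for nid in {r["nutrient_id"] for r in drv_rows}:
        rows = [r for r in drv_rows if r["nutrient_id"] == nid]
        by_stratum = {(r["sex"], r["age_group"]): r for r in rows}
        t = lo = up = 0.0
        lo_ok = up_ok = True
        for (sex, age), p in sexage_pop.items():
            r = by_stratum[(sex, age)]
            target = _f(r["target"])
            if diet_mode == "vegetarian" and r["alt_target_vegetarian"] not in ("", None):
                target = _f(r["alt_target_vegetarian"])
            if diet_mode == "vegan" and r["alt_target_vegan"] not in ("", None):
                target = _f(r["alt_target_vegan"])
            w = p / population
            t += w * target
            if r["lower_safe"] in ("", None):
                lo_ok = False
            else:
                lo += w * _f(r["lower_safe"])
            if r["upper_safe"] in ("", None):
                up_ok = False
            else:
                up += w * _f(r["upper_safe"])
        targets[nid] = t
        lowers[nid] = lo if lo_ok else math.nan
        uppers[nid] = up if up_ok else math.nan

    gap_pct = {
        n: max(0.0, 100.0 * (targets[n] - supply.get(n, 0.0)) / targets[n])
        for n in targets
    }
    return {
        "baseline_year": baseline_year,
        "population": population,
        "diet_mode": diet_mode,
        "items": result_items,
        "total_biomass": sum(production.values()),
        "supply": supply,
        "wasted": wasted,
        "targets": targets,
        "lower_safe": lowers,
        "upper_safe": uppers,
        "gap_pct": gap_pct,
    }
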