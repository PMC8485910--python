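"""Schema-validated readers and writers for every model table and report.

All tables are UTF-8 CSV with a single header row, decimal point, and no
thousands separators.  Group, region, nutrient and age-group vocabularies
are data-driven: they are declared by ``groups.csv`` / ``regions.csv`` and
by the columns of ``items.csv`` / rows of ``drv.csv``, never hard-coded.

Nutrient density columns in ``items.csv`` are named ``<nutrient_id>[<unit>]``
(e.g. ``calcium[mg]``) so that units travel with the data; digestibility
columns are named ``dig:<nutrient_id>`` and are only meaningful for protein
and the indispensable amino acids (all other nutrients default to 1.0).
Units must agree with the ``unit`` column of ``drv.csv`` — enforced at load
time, no unit conversion is ever performed.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class DeltaError(Exception):
    """Base class for all model errors."""


class SchemaError(DeltaError):
    """A table is missing a required column or has an unparseable header."""


class DataValidationError(DeltaError):
    """A record violates a type invariant; the message names its keys."""


class UnknownVocabularyError(DataValidationError):
    """A record references a group/region/item absent from the vocabulary."""


class UnitMismatchError(DataValidationError):
    """Composition and DRV tables disagree on a nutrient's unit."""


# ---------------------------------------------------------------------------
# Schemas
# ---------------------------------------------------------------------------

BALANCE_COLUMNS = [
    "item_id", "group_id", "year",
    "production_t", "feed_t", "supply_chain_loss_t", "nonfood_t",
]
ITEM_FIXED_COLUMNS = ["item_id", "group_id", "origin", "inedible_fraction"]
WASTE_COLUMNS = ["region_id", "group_id", "waste_fraction"]
DEMOGRAPHICS_COLUMNS = ["region_id", "sex", "age_group", "year", "population"]
DRV_COLUMNS = [
    "nutrient_id", "sex", "age_group", "target",
    "lower_safe", "upper_safe", "unit",
    "alt_target_vegetarian", "alt_target_vegan",
]
GROUPS_COLUMNS = ["group_id", "origin", "vegetarian_ok"]

MASS_REPORT_COLUMNS = [
    "item_id", "group_id", "production_t", "feed_t", "supply_chain_loss_t",
    "nonfood_t", "inedible_t", "in_home_waste_t", "consumed_edible_t",
    "per_capita_g_day",
]
NUTRIENT_REPORT_COLUMNS = [
    "nutrient_id", "unit", "supply", "target", "lower_safe", "upper_safe",
    "pct_of_target", "gap_pct", "excess_pct", "material",
]
WASTE_REPORT_COLUMNS = [
    "nutrient_id", "wasted_amount", "pct_of_target",
    "plant_share_pct", "animal_share_pct",
]
DELTA_REPORT_COLUMNS = [
    "nutrient_id", "supply_a", "supply_b", "delta_supply", "delta_gap_pct",
]

_DENSITY_RE = re.compile(r"^(?P<nid>[A-Za-z0-9_\-]+)\[(?P<unit>[^\[\]]+)\]$")
_DIG_RE = re.compile(r"^dig:(?P<nid>[A-Za-z0-9_\-]+)$")

SEXES = ("F", "M")
ORIGINS = ("plant", "animal")


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# Scenario model
# ---------------------------------------------------------------------------


class GroupChange(BaseModel):
    """Production override for one food group: absolute tons or a multiplier."""

    tons: float | None = Field(default=None, ge=0)
    multiplier: float | None = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _exactly_one_form(self) -> "GroupChange":
        if self.tons is not None and self.multiplier is not None:
            raise ValueError("give either 'tons' or 'multiplier' for a group, not both")
        return self


class Scenario(BaseModel):
    """A user-specified food-system scenario, before resolution.

    Unnamed groups default to multiplier 1 (baseline production); both waste
    multipliers default to 1; nonfood use defaults to per-capita-constant
    scaling; diet mode defaults to automatic detection.
    """

    name: str = "scenario"
    population_year: int | None = None
    groups: dict[str, GroupChange] = Field(default_factory=dict)
    zero_groups: list[str] = Field(default_factory=list)
    compensation_factor: float = Field(default=1.0, ge=0)
    remove_group: str | None = None
    recipients: list[str] | None = None
    supply_chain_waste_multiplier: float = Field(default=1.0, ge=0)
    in_home_waste_multiplier: float = Field(default=1.0, ge=0)
    nonfood_mode: Literal["per_capita_constant", "proportional_to_production"] = (
        "per_capita_constant"
    )
    diet_mode: Literal["auto", "omnivore", "vegetarian", "vegan"] = "auto"

    def validate_groups(self, known_groups: set[str]) -> None:
        referenced = (
            set(self.groups) | set(self.zero_groups)
            | ({self.remove_group} if self.remove_group else set())
            | set(self.recipients or [])
        )
        unknown = sorted(referenced - known_groups)
        if unknown:
            raise UnknownVocabularyError(
                f"scenario '{self.name}' references unknown group(s) {unknown}"
            )


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """All validated input tables for one model world.

    ``densities`` and ``digestibility`` are item × nutrient frames (per 100 g
    of edible portion); digestibility is 1.0 wherever the source table gave
    no coefficient.
    """

    balance: pd.DataFrame
    items: pd.DataFrame              # item_id-indexed: group_id, origin, inedible_fraction
    densities: pd.DataFrame          # item × nutrient
    digestibility: pd.DataFrame      # item × nutrient, default 1.0
    nutrient_units: dict[str, str]
    waste: pd.DataFrame              # region_id, group_id, waste_fraction
    demographics: pd.DataFrame
    drv: pd.DataFrame
    groups: pd.DataFrame             # group_id-indexed: origin, vegetarian_ok
    regions: list[str] = field(default_factory=list)

    @property
    def group_ids(self) -> set[str]:
        return set(self.groups.index)

    @property
    def nutrient_ids(self) -> list[str]:
        return list(self.densities.columns)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_groups(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"group_id": str, "origin": str})
    _require_columns(df, GROUPS_COLUMNS, "groups")
    dup = df["group_id"][df["group_id"].duplicated()]
    if not dup.empty:
        raise DataValidationError(f"groups: duplicate group_id {sorted(dup)}")
    bad = df.loc[~df["origin"].isin(ORIGINS), "group_id"]
    if not bad.empty:
        raise DataValidationError(
            f"groups: origin must be one of {ORIGINS} for group(s) {sorted(bad)}"
        )
    truth = {"true": True, "false": False, "1": True, "0": False}
    try:
        df["vegetarian_ok"] = [
            truth[str(v).strip().lower()] for v in df["vegetarian_ok"]
        ]
    except KeyError as exc:
        raise DataValidationError(f"groups: vegetarian_ok not boolean: {exc}") from exc
    return df.set_index("group_id")


def read_regions(path: Path | str) -> list[str]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["region_id"], "regions")
    regions = df["region_id"].tolist()
    if len(set(regions)) != len(regions):
        raise DataValidationError("regions: duplicate region_id")
    return regions


def read_balance_table(path: Path | str, known_groups: set[str] | None = None) -> pd.DataFrame:
    """Read a commodity balance table (item × year farm-gate masses, tons/yr)."""
    df = pd.read_csv(path, dtype={"item_id": str, "group_id": str})
    _require_columns(df, BALANCE_COLUMNS, "balance")
    df = df[BALANCE_COLUMNS].copy()
    df["year"] = df["year"].astype(int)

    dup = df[df.duplicated(["item_id", "year"], keep=False)]
    if not dup.empty:
        keys = sorted({(r.item_id, r.year) for r in dup.itertuples()})
        raise DataValidationError(f"balance: duplicate (item_id, year) {keys}")

    masses = df[["production_t", "feed_t", "supply_chain_loss_t", "nonfood_t"]]
    numeric = masses.apply(pd.to_numeric, errors="coerce")
    nonfinite = df[~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan)).all(axis=1)]
    if not nonfinite.empty:
        r = nonfinite.iloc[0]
        raise DataValidationError(
            f"balance: non-finite mass for (item_id={r.item_id}, year={r.year})"
        )
    neg = df[(masses < 0).any(axis=1)]
    if not neg.empty:
        r = neg.iloc[0]
        raise DataValidationError(
            f"balance: negative mass for (item_id={r.item_id}, year={r.year})"
        )
    util = df["feed_t"] + df["supply_chain_loss_t"] + df["nonfood_t"]
    over = df[util > df["production_t"] * (1 + 1e-12)]
    if not over.empty:
        r = over.iloc[0]
        raise DataValidationError(
            "balance: feed+loss+nonfood exceeds production for "
            f"(item_id={r.item_id}, year={r.year})"
        )
    if known_groups is not None:
        unknown = sorted(set(df["group_id"]) - known_groups)
        if unknown:
            raise UnknownVocabularyError(f"balance: unknown group_id {unknown}")
    item_groups = df.groupby("item_id")["group_id"].nunique()
    multi = item_groups[item_groups > 1]
    if not multi.empty:
        raise DataValidationError(
            f"balance: item(s) assigned to more than one group {sorted(multi.index)}"
        )
    return df.sort_values(["item_id", "year"]).reset_index(drop=True)


def read_items(
    path: Path | str,
    known_groups: set[str] | None = None,
    drv_units: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Read item profiles.

    Returns ``(items, densities, digestibility, nutrient_units)`` where the
    last three are derived from the ``<nutrient>[unit]`` / ``dig:<nutrient>``
    columns.  If ``drv_units`` is given, units are checked for equality.
    """
    df = pd.read_csv(path, dtype={"item_id": str, "group_id": str, "origin": str})
    _require_columns(df, ITEM_FIXED_COLUMNS, "items")

    dup = df["item_id"][df["item_id"].duplicated()]
    if not dup.empty:
        raise DataValidationError(f"items: duplicate item_id {sorted(dup)}")

    nutrient_units: dict[str, str] = {}
    density_cols: dict[str, str] = {}
    dig_cols: dict[str, str] = {}
    for col in df.columns:
        if col in ITEM_FIXED_COLUMNS:
            continue
        m = _DENSITY_RE.match(col)
        if m:
            nutrient_units[m["nid"]] = m["unit"]
            density_cols[m["nid"]] = col
            continue
        m = _DIG_RE.match(col)
        if m:
            dig_cols[m["nid"]] = col
            continue
        raise SchemaError(
            f"items: unrecognised column '{col}' "
            "(expected '<nutrient>[unit]' or 'dig:<nutrient>')"
        )
    unknown_dig = sorted(set(dig_cols) - set(density_cols))
    if unknown_dig:
        raise SchemaError(f"items: digestibility for unknown nutrient(s) {unknown_dig}")

    items = df[ITEM_FIXED_COLUMNS].set_index("item_id")
    bad = items[~items["origin"].isin(ORIGINS)]
    if not bad.empty:
        raise DataValidationError(
            f"items: origin must be one of {ORIGINS} for item(s) {sorted(bad.index)}"
        )
    out_of_range = items[
        (items["inedible_fraction"] < 0) | (items["inedible_fraction"] > 1)
    ]
    if not out_of_range.empty:
        raise DataValidationError(
            f"items: inedible_fraction outside [0,1] for item(s) {sorted(out_of_range.index)}"
        )

    densities = df.set_index("item_id")[list(density_cols.values())].astype(float)
    densities.columns = list(density_cols.keys())
    if (densities < 0).any().any():
        bad_items = sorted(densities.index[(densities < 0).any(axis=1)])
        raise DataValidationError(f"items: negative nutrient density for item(s) {bad_items}")

    digestibility = pd.DataFrame(1.0, index=densities.index, columns=densities.columns)
    for nid, col in dig_cols.items():
        vals = df.set_index("item_id")[col].astype(float)
        if ((vals < 0) | (vals > 1)).any():
            bad_items = sorted(vals.index[(vals < 0) | (vals > 1)])
            raise DataValidationError(
                f"items: digestibility outside [0,1] for item(s) {bad_items} (nutrient {nid})"
            )
        digestibility[nid] = vals.fillna(1.0)

    if known_groups is not None:
        unknown = sorted(set(items["group_id"]) - known_groups)
        if unknown:
            raise UnknownVocabularyError(f"items: unknown group_id {unknown}")
    if drv_units is not None:
        for nid, unit in nutrient_units.items():
            if nid in drv_units and drv_units[nid] != unit:
                raise UnitMismatchError(
                    f"nutrient '{nid}': items table uses unit '{unit}' "
                    f"but DRV table uses '{drv_units[nid]}'"
                )
    return items, densities, digestibility, nutrient_units


def read_waste(
    path: Path | str,
    known_regions: set[str] | None = None,
    known_groups: set[str] | None = None,
) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"region_id": str, "group_id": str})
    _require_columns(df, WASTE_COLUMNS, "waste")
    dup = df[df.duplicated(["region_id", "group_id"], keep=False)]
    if not dup.empty:
        keys = sorted({(r.region_id, r.group_id) for r in dup.itertuples()})
        raise DataValidationError(f"waste: duplicate (region_id, group_id) {keys}")
    bad = df[(df["waste_fraction"] < 0) | (df["waste_fraction"] > 1)]
    if not bad.empty:
        r = bad.iloc[0]
        raise DataValidationError(
            f"waste: waste_fraction outside [0,1] for (region_id={r.region_id}, "
            f"group_id={r.group_id})"
        )
    if known_regions is not None:
        unknown = sorted(set(df["region_id"]) - known_regions)
        if unknown:
            raise UnknownVocabularyError(f"waste: unknown region_id {unknown}")
    if known_groups is not None:
        unknown = sorted(set(df["group_id"]) - known_groups)
        if unknown:
            raise UnknownVocabularyError(f"waste: unknown group_id {unknown}")
    return df.reset_index(drop=True)


def read_demographics(path: Path | str, known_regions: set[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"region_id": str, "sex": str, "age_group": str})
    _require_columns(df, DEMOGRAPHICS_COLUMNS, "demographics")
    df["year"] = df["year"].astype(int)
    dup = df[df.duplicated(["region_id", "sex", "age_group", "year"], keep=False)]
    if not dup.empty:
        keys = sorted({(r.region_id, r.sex, r.age_group, r.year) for r in dup.itertuples()})
        raise DataValidationError(f"demographics: duplicate stratum rows {keys}")
    bad_sex = df[~df["sex"].isin(SEXES)]
    if not bad_sex.empty:
        raise DataValidationError(
            f"demographics: sex must be one of {SEXES}, got {sorted(set(bad_sex['sex']))}"
        )
    neg = df[df["population"] < 0]
    if not neg.empty:
        r = neg.iloc[0]
        raise DataValidationError(
            f"demographics: negative population for (region_id={r.region_id}, "
            f"sex={r.sex}, age_group={r.age_group}, year={r.year})"
        )
    if known_regions is not None:
        unknown = sorted(set(df["region_id"]) - known_regions)
        if unknown:
            raise UnknownVocabularyError(f"demographics: unknown region_id {unknown}")
    return df.reset_index(drop=True)


def read_drv(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"nutrient_id": str, "sex": str, "age_group": str, "unit": str})
    _require_columns(df, DRV_COLUMNS, "drv")
    dup = df[df.duplicated(["nutrient_id", "sex", "age_group"], keep=False)]
    if not dup.empty:
        keys = sorted({(r.nutrient_id, r.sex, r.age_group) for r in dup.itertuples()})
        raise DataValidationError(f"drv: duplicate (nutrient_id, sex, age_group) {keys}")
    nonpos = df[df["target"] <= 0]
    if not nonpos.empty:
        r = nonpos.iloc[0]
        raise DataValidationError(
            f"drv: target must be > 0 for (nutrient_id={r.nutrient_id}, sex={r.sex}, "
            f"age_group={r.age_group})"
        )
    bad = pd.concat([
        df[df["lower_safe"].notna() & (df["lower_safe"] > df["target"])],
        df[df["upper_safe"].notna() & (df["upper_safe"] < df["target"])],
    ])
    if not bad.empty:
        r = bad.iloc[0]
        raise DataValidationError(
            f"drv: lower_safe <= target <= upper_safe violated for "
            f"(nutrient_id={r.nutrient_id}, sex={r.sex}, age_group={r.age_group})"
        )
    for col in ("alt_target_vegetarian", "alt_target_vegan"):
        bad = df[df[col].notna() & (df[col] < df["target"])]
        if not bad.empty:
            r = bad.iloc[0]
            raise DataValidationError(
                f"drv: {col} below default target for (nutrient_id={r.nutrient_id}, "
                f"sex={r.sex}, age_group={r.age_group})"
            )
    units = df.groupby("nutrient_id")["unit"].nunique()
    multi = units[units > 1]
    if not multi.empty:
        raise DataValidationError(f"drv: inconsistent unit within nutrient(s) {sorted(multi.index)}")
    return df.reset_index(drop=True)


def read_scenario(path: Path | str, known_groups: set[str] | None = None) -> Scenario:
    """Read a scenario definition from a YAML (or JSON) document."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise SchemaError(f"scenario file {path}: expected a mapping at top level")
    waste = doc.pop("waste", None)
    if waste:
        if "supply_chain" in waste:
            doc["supply_chain_waste_multiplier"] = waste["supply_chain"]
        if "in_home" in waste:
            doc["in_home_waste_multiplier"] = waste["in_home"]
    groups = doc.get("groups") or {}
    doc["groups"] = {
        gid: (spec if isinstance(spec, dict) else {"multiplier": spec})
        for gid, spec in groups.items()
    }
    try:
        sc = Scenario(**doc)
    except (ValueError, TypeError) as exc:
        raise DataValidationError(f"scenario file {path}: {exc}") from exc
    if known_groups is not None:
        sc.validate_groups(known_groups)
    return sc


def load_dataset(data_dir: Path | str) -> Dataset:
    """Load and cross-validate a complete data directory."""
    d = Path(data_dir)
    groups = read_groups(d / "groups.csv")
    regions = read_regions(d / "regions.csv")
    drv = read_drv(d / "drv.csv")
    drv_units = drv.drop_duplicates("nutrient_id").set_index("nutrient_id")["unit"].to_dict()
    items, densities, digestibility, nutrient_units = read_items(
        d / "items.csv", known_groups=set(groups.index), drv_units=drv_units
    )
    # item origin must agree with its group's origin
    merged = items.join(groups["origin"], on="group_id", rsuffix="_group")
    mismatch = merged[merged["origin"] != merged["origin_group"]]
    if not mismatch.empty:
        raise DataValidationError(
            f"items: origin disagrees with group origin for item(s) {sorted(mismatch.index)}"
        )
    balance = read_balance_table(d / "balance.csv", known_groups=set(groups.index))
    unknown_items = sorted(set(balance["item_id"]) - set(items.index))
    if unknown_items:
        raise UnknownVocabularyError(f"balance: item(s) without profile {unknown_items}")
    waste = read_waste(
        d / "waste.csv", known_regions=set(regions), known_groups=set(groups.index)
    )
    demographics = read_demographics(d / "demographics.csv", known_regions=set(regions))
    return Dataset(
        balance=balance, items=items, densities=densities,
        digestibility=digestibility, nutrient_units=nutrient_units,
        waste=waste, demographics=demographics, drv=drv,
        groups=groups, regions=regions,
    )


def convert_fao_download(path: Path | str) -> pd.DataFrame:
    """Converter stub for FAO-native download dialects.

    The model consumes the plain CSV schema documented in this module; the
    FAO website's own export formats (wide element-code layouts, locale
    separators) are out of scope.  Prepare data externally by mapping FBS
    elements to the ``production_t`` / ``feed_t`` / ``supply_chain_loss_t`` /
    ``nonfood_t`` columns, one row per (item, year).
    """
    raise NotImplementedError(
        "FAO-native formats are not parsed; reshape the download to the "
        "balance.csv schema (see module docstring) before loading."
    )


# ---------------------------------------------------------------------------
# Report writers
# ---------------------------------------------------------------------------


def _frame_to_csv(df: pd.DataFrame, path: Path) -> None:
    # default float repr is shortest-exact, so identical inputs give
    # byte-identical files
    df.to_csv(path, index=False, lineterminator="\n")


def write_reports(
    mass_report: pd.DataFrame,
    nutrient_report: pd.DataFrame,
    waste_report: pd.DataFrame,
    out_dir: Path | str,
    format: Literal["csv", "json"] = "csv",
) -> list[Path]:
    """Write the three scenario reports with a stable column and row order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mass = mass_report[MASS_REPORT_COLUMNS].sort_values("item_id").reset_index(drop=True)
    nutr = nutrient_report[NUTRIENT_REPORT_COLUMNS].sort_values("nutrient_id").reset_index(drop=True)
    waste = waste_report[WASTE_REPORT_COLUMNS].sort_values("nutrient_id").reset_index(drop=True)
    if format == "csv":
        paths = [out / "mass_report.csv", out / "nutrient_report.csv", out / "waste_report.csv"]
        for df, p in zip((mass, nutr, waste), paths):
            _frame_to_csv(df, p)
        return paths
    if format == "json":
        doc = {
            "mass_report": _records(mass),
            "nutrient_report": _records(nutr),
            "waste_report": _records(waste),
        }
        p = out / "report.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True, allow_nan=False)
            fh.write("\n")
        return [p]
    raise ValueError(f"unknown report format '{format}'")


def _records(df: pd.DataFrame) -> list[dict]:
    recs = []
    for rec in df.to_dict(orient="records"):
        recs.append({k: (None if pd.isna(v) else v) for k, v in rec.items()})
    return recs


def write_delta_report(deltas: Mapping[str, pd.DataFrame], out_file: Path | str) -> list[Path]:
    """Write scenario-comparison output.

    The nutrient deltas go to ``out_file`` with the documented columns; the
    per-group biomass deltas go to a sibling ``<stem>_groups.csv``.
    """
    out = Path(out_file)
    out.parent.mkdir(parents=True, exist_ok=True)
    _frame_to_csv(deltas["nutrients"][DELTA_REPORT_COLUMNS], out)
    groups_path = out.with_name(out.stem + "_groups.csv")
    _frame_to_csv(deltas["groups"], groups_path)
    return [out, groups_path]
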