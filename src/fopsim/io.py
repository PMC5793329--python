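"""Data model and delimited-text IO for food composition, recall and participant tables.

The pipeline works with three input tables plus criteria configs:

* a food-composition table: one row per food, energy and nutrient content per
  100 g or 100 mL, a category label, and a processed flag;
* a 24-hour-recall table: one row per (person, food) with the amount consumed;
* a participant table: survey design fields (weight, stratum, PSU) and the
  covariates used for exclusion filters and subgroup summaries.

All files are UTF-8 delimited text with a header row (comma by default, tab
via ``delimiter="\\t"``).  Missing optional nutrient values stay missing
(``None`` / ``NaN``); they are never silently coerced to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

#: canonical nutrient name -> food-table column name
NUTRIENT_COLUMNS: dict[str, str] = {
    "energy": "energy_kcal",
    "saturated_fat": "satfat_g",
    "trans_fat": "transfat_g",
    "total_fat": "totalfat_g",
    "total_sugar": "sugar_total_g",
    "added_sugar": "sugar_added_g",
    "sodium": "sodium_mg",
    "fiber": "fiber_g",
}

#: nutrients reported in intake summaries (daily units: kcal, g, g, g, mg, g)
REPORT_NUTRIENTS: tuple[str, ...] = (
    "energy",
    "saturated_fat",
    "trans_fat",
    "total_sugar",
    "sodium",
    "fiber",
)

VALID_BASES = ("per_100_g", "per_100_mL")
_BASIS_ALIASES = {
    "per_100_g": "per_100_g",
    "per_100_ml": "per_100_mL",
    "g": "per_100_g",
    "ml": "per_100_mL",
    "100g": "per_100_g",
    "100ml": "per_100_mL",
}

PARTICIPANT_COLUMNS = (
    "person_id",
    "weight",
    "stratum",
    "psu",
    "sex",
    "age",
    "bmi",
    "region",
    "locality",
    "ses",
    "pregnant_or_lactating",
)


@dataclass(frozen=True)
class NutrientProfile:
    """Energy and nutrient content per 100 basis units (g or mL) of a food.

    ``None`` marks a value missing from the composition source; rules that
    read a missing nutrient fail conservatively rather than crash.
    """

    energy: float | None = None
    saturated_fat: float | None = None
    trans_fat: float | None = None
    total_fat: float | None = None
    total_sugar: float | None = None
    added_sugar: float | None = None
    sodium: float | None = None
    fiber: float | None = None

    def get(self, nutrient: str) -> float | None:
        return getattr(self, nutrient)

    def validate(self, context: str = "") -> None:
        """Raise :class:`DataError` on a negative value or an impossible combination."""
        where = f" ({context})" if context else ""
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and v < 0:
                raise DataError(f"negative {f.name} value {v}{where}")
        if (
            self.added_sugar is not None
            and self.total_sugar is not None
            and self.added_sugar > self.total_sugar + 1e-9
        ):
            raise DataError(
                f"added_sugar {self.added_sugar} exceeds total_sugar "
                f"{self.total_sugar}{where}: added sugar must be <= total sugar"
            )
        if self.total_fat is not None:
            sat = self.saturated_fat or 0.0
            trans = self.trans_fat or 0.0
            if sat + trans > self.total_fat + 1e-9:
                raise DataError(
                    f"saturated_fat + trans_fat = {sat + trans} exceeds "
                    f"total_fat {self.total_fat}{where}"
                )


@dataclass(frozen=True)
class FoodItem:
    """A food with its category, processing status and per-100 nutrient profile."""

    food_id: str
    name: str
    category: str
    processed: bool
    basis: str = "per_100_g"
    serving_size: float | None = None
    profile: NutrientProfile = field(default_factory=NutrientProfile)

    def __post_init__(self) -> None:
        if self.basis not in VALID_BASES:
            raise DataError(
                f"unknown basis token {self.basis!r} for food {self.food_id!r}; "
                f"expected one of {VALID_BASES}"
            )
        if self.processed and not self.category:
            raise DataError(f"processed food {self.food_id!r} has no category")

    @property
    def energy_density(self) -> float | None:
        """kcal per 100 basis units."""
        return self.profile.energy


class FoodDatabase:
    """Collection of :class:`FoodItem` keyed by ``food_id`` (unique)."""

    def __init__(self, items: Iterable[FoodItem] = ()):
        self._items: dict[str, FoodItem] = {}
        for item in items:
            self.add(item)

    def add(self, item: FoodItem) -> None:
        if item.food_id in self._items:
            raise DataError(f"duplicate food_id {item.food_id!r}")
        self._items[item.food_id] = item

    def __getitem__(self, food_id: str) -> FoodItem:
        try:
            return self._items[food_id]
        except KeyError:
            raise KeyError(f"food_id {food_id!r} not in database") from None

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._items

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[FoodItem]:
        return iter(self._items.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoodDatabase):
            return NotImplemented
        return self._items == other._items

    @property
    def food_ids(self) -> list[str]:
        return list(self._items)

    def processed_foods(self) -> list[FoodItem]:
        return [f for f in self if f.processed]

    def categories(self) -> set[str]:
        return {f.category for f in self if f.category}

    def to_frame(self) -> pd.DataFrame:
        """Food table as a DataFrame in the on-disk column layout."""
        rows = []
        for f in self:
            row: dict[str, object] = {
                "food_id": f.food_id,
                "name": f.name,
                "category": f.category,
                "processed": f.processed,
                "basis": f.basis,
                "serving_size": f.serving_size,
            }
            for nutrient, col in NUTRIENT_COLUMNS.items():
                row[col] = f.profile.get(nutrient)
            rows.append(row)
        cols = ["food_id", "name", "category", "processed", "basis", "serving_size"]
        cols += list(NUTRIENT_COLUMNS.values())
        return pd.DataFrame(rows, columns=cols)


def _parse_bool(value: object, row: int, column: str) -> bool:
    token = str(value).strip().lower()
    if token in ("true", "1", "yes", "t"):
        return True
    if token in ("false", "0", "no", "f"):
        return False
    raise DataError(f"row {row}: cannot parse {column}={value!r} as boolean")


def _parse_optional_float(value: object, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan", "none"):
        return None
    try:
        return float(s)
    except ValueError:
        raise DataError(f"row {row}: cannot parse {column}={value!r} as number") from None


def load_food_db(
    path,
    basis_column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> FoodDatabase:
    """Read a food-composition table into a validated :class:`FoodDatabase`.

    Parameters
    ----------
    path
        Delimited-text file with a header row.
    basis_column_map
        Optional mapping from the canonical column names
        (``food_id``, ``name``, ``category``, ``processed``, ``basis``,
        ``serving_size`` and the nutrient columns of
        :data:`NUTRIENT_COLUMNS`) to the names used in the file.
    delimiter
        Field delimiter; comma by default, ``"\\t"`` for tab-delimited files.

    Raises
    ------
    DataError
        On duplicate ``food_id`` (naming the id), a negative nutrient value
        (with its row number), an unknown basis token, or a profile violating
        a composition invariant.  Row numbers count data rows from 1.
    """
    colmap = dict(basis_column_map or {})
    raw = pd.read_csv(path, sep=delimiter, dtype=str)

    def col(name: str) -> str:
        return colmap.get(name, name)

    required = ["food_id", "name", "category", "processed", "basis"]
    missing = [col(c) for c in required if col(c) not in raw.columns]
    if missing:
        raise DataError(f"food table {path} is missing columns {missing}")

    db = FoodDatabase()
    for i, rec in enumerate(raw.to_dict("records"), start=1):
        food_id = str(rec[col("food_id")]).strip()
        basis_token = str(rec[col("basis")]).strip().lower()
        basis = _BASIS_ALIASES.get(basis_token)
        if basis is None:
            raise DataError(
                f"row {i}: unknown basis token {rec[col('basis')]!r} "
                f"for food {food_id!r}"
            )
        profile_values = {
            nutrient: _parse_optional_float(rec.get(col(colname)), i, colname)
            for nutrient, colname in NUTRIENT_COLUMNS.items()
        }
        profile = NutrientProfile(**profile_values)
        profile.validate(context=f"row {i}, food {food_id!r}")
        serving_col = col("serving_size")
        serving = (
            _parse_optional_float(rec.get(serving_col), i, "serving_size")
            if serving_col in raw.columns
            else None
        )
        item = FoodItem(
            food_id=food_id,
            name=str(rec[col("name")]).strip(),
            category=str(rec[col("category")]).strip(),
            processed=_parse_bool(rec[col("processed")], i, "processed"),
            basis=basis,
            serving_size=serving,
            profile=profile,
        )
        db.add(item)
    logger.info("loaded food database: %d items from %s", len(db), path)
    return db


def write_food_db(db: FoodDatabase, path, delimiter: str = ",") -> None:
    db.to_frame().to_csv(path, sep=delimiter, index=False)


def load_recalls(path, food_db: FoodDatabase, delimiter: str = ",") -> pd.DataFrame:
    """Read a 24HR recall table (``person_id,food_id,amount``).

    Every ``food_id`` must resolve in ``food_db`` and every amount must be a
    positive real; violations raise :class:`DataError` listing all offending
    ids / row numbers.  An empty table (header only) yields an empty frame
    with a logged warning.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype={"person_id": str, "food_id": str})
    missing_cols = [c for c in ("person_id", "food_id", "amount") if c not in raw.columns]
    if missing_cols:
        raise DataError(f"recall table {path} is missing columns {missing_cols}")
    if raw.empty:
        logger.warning("recall table %s contains no entries", path)
        return raw

    unknown = sorted(set(raw["food_id"]) - set(food_db.food_ids))
    if unknown:
        raise DataError(f"recall table references unknown food ids: {unknown}")
    amounts = pd.to_numeric(raw["amount"], errors="coerce")
    bad = raw.index[~(amounts > 0)]
    if len(bad):
        rows = [int(i) + 1 for i in bad[:10]]
        raise DataError(
            f"recall table has non-positive or unparseable amounts at data rows {rows}"
        )
    out = raw.copy()
    out["amount"] = amounts.astype(float)
    logger.info(
        "loaded recalls: %d entries, %d persons from %s",
        len(out),
        out["person_id"].nunique(),
        path,
    )
    return out


def write_recalls(recalls: pd.DataFrame, path, delimiter: str = ",") -> None:
    recalls.to_csv(path, sep=delimiter, index=False)


def load_participants(path, delimiter: str = ",") -> pd.DataFrame:
    """Read the participant table (design fields + covariates).

    Survey weights must be strictly positive.  ``age``, ``bmi`` may be
    missing (the exclusion stage counts them under ``missing_data``).
    """
    raw = pd.read_csv(path, sep=delimiter, dtype={"person_id": str})
    missing_cols = [c for c in PARTICIPANT_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise DataError(f"participant table {path} is missing columns {missing_cols}")
    if raw["person_id"].duplicated().any():
        dups = raw.loc[raw["person_id"].duplicated(), "person_id"].tolist()
        raise DataError(f"duplicate person_id values: {sorted(set(dups))}")
    out = raw.copy()
    out["weight"] = pd.to_numeric(out["weight"], errors="coerce")
    if not (out["weight"] > 0).all():
        bad = [int(i) + 1 for i in out.index[~(out["weight"] > 0)][:10]]
        raise DataError(f"non-positive survey weights at data rows {bad}")
    for c in ("age", "bmi"):
        out[c] = pd.to_numeric(out[c], errors="coerce")
    out["pregnant_or_lactating"] = [
        _parse_bool(v, i + 1, "pregnant_or_lactating")
        for i, v in enumerate(out["pregnant_or_lactating"])
    ]
    return out


def write_participants(participants: pd.DataFrame, path, delimiter: str = ",") -> None:
    participants.to_csv(path, sep=delimiter, index=False)


def write_scenario_table(results: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a scenario-summary table (one row per nutrient x scenario).

    ``results`` must carry the columns ``scenario``, ``nutrient``, ``median``,
    ``p25``, ``p75``, ``percent_change``, ``p_value`` (extra columns such as a
    grouping variable are preserved).  Numeric columns round-trip through
    :func:`read_scenario_table` to at least 6 significant digits.
    """
    required = {"scenario", "nutrient", "median", "p25", "p75", "percent_change", "p_value"}
    missing = required - set(results.columns)
    if missing:
        raise DataError(f"scenario table is missing columns {sorted(missing)}")
    results.to_csv(path, sep=delimiter, index=False, float_format="%.10g")


def read_scenario_table(path, delimiter: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter)


def food_from_row(row: Mapping[str, object]) -> FoodItem:
    """Build a :class:`FoodItem` from an in-memory mapping in the on-disk layout."""
    profile = NutrientProfile(
        **{nutrient: row.get(colname) for nutrient, colname in NUTRIENT_COLUMNS.items()}
    )
    profile.validate(context=f"food {row.get('food_id')!r}")
    return FoodItem(
        food_id=str(row["food_id"]),
        name=str(row.get("name", row["food_id"])),
        category=str(row.get("category", "")),
        processed=bool(row.get("processed", True)),
        basis=str(row.get("basis", "per_100_g")),
        serving_size=row.get("serving_size"),
        profile=profile,
    )


__all__ = [
    "NUTRIENT_COLUMNS",
    "REPORT_NUTRIENTS",
    "VALID_BASES",
    "PARTICIPANT_COLUMNS",
    "NutrientProfile",
    "FoodItem",
    "FoodDatabase",
    "load_food_db",
    "write_food_db",
    "load_recalls",
    "write_recalls",
    "load_participants",
    "write_participants",
    "write_scenario_table",
    "read_scenario_table",
    "food_from_row",
]
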