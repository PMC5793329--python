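"""Declarative nutrient-profiling criteria and food classification.

A criteria set is a named collection of per-category rules.  Each rule says
whether the category is *eligible* to carry the front-of-package logo at all
(sugar-based categories are ineligible under COFEPRIS-style regulation) and
lists thresholds of the form ``nutrient cmp limit per denominator``, e.g.
``saturated_fat <= 10 pct_of_energy``.  A food complies when its category is
eligible and every threshold passes; comparators are inclusive.

Denominators
------------
``per_100_basis``
    Read the per-100 g/mL profile value directly.
``per_serving``
    profile value x serving_size / 100.
``pct_of_energy``
    100 x k x grams / energy_kcal with the Atwater factors k = 9 kcal/g for
    fats and k = 4 kcal/g for sugars.
``pct_of_total_fat``
    100 x nutrient grams / total_fat grams.

A threshold that cannot be evaluated (missing nutrient, missing serving
size, zero energy or zero total fat in a percentage denominator) fails
conservatively with a logged reason: an unverifiable food never counts as
compliant and is never offered as a replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from .errors import CriteriaError
from .io import FoodDatabase, FoodItem

logger = logging.getLogger(__name__)

KNOWN_NUTRIENTS = (
    "energy",
    "saturated_fat",
    "trans_fat",
    "total_fat",
    "total_sugar",
    "added_sugar",
    "sodium",
    "fiber",
)
KNOWN_DENOMINATORS = ("per_100_basis", "per_serving", "pct_of_energy", "pct_of_total_fat")

#: kcal per gram used for %-of-energy denominators (Atwater)
ENERGY_FACTORS = {
    "saturated_fat": 9.0,
    "trans_fat": 9.0,
    "total_fat": 9.0,
    "total_sugar": 4.0,
    "added_sugar": 4.0,
}
_FAT_NUTRIENTS = ("saturated_fat", "trans_fat")


@dataclass(frozen=True)
class Threshold:
    nutrient: str
    cmp: str  # "le" or "ge"
    limit: float
    per: str = "per_100_basis"

    def __post_init__(self) -> None:
        if self.nutrient not in KNOWN_NUTRIENTS:
            raise CriteriaError(f"unknown nutrient {self.nutrient!r}")
        if self.per not in KNOWN_DENOMINATORS:
            raise CriteriaError(f"unknown denominator {self.per!r}")
        if self.cmp not in ("le", "ge"):
            raise CriteriaError(f"unknown comparator {self.cmp!r} (expected 'le' or 'ge')")
        if self.limit < 0:
            raise CriteriaError(f"negative limit {self.limit} for {self.nutrient}")
        if self.cmp == "ge" and self.nutrient != "fiber":
            raise CriteriaError(
                f">= comparator is only supported for fiber, not {self.nutrient!r}"
            )
        if self.per == "pct_of_energy" and self.nutrient not in ENERGY_FACTORS:
            raise CriteriaError(
                f"pct_of_energy denominator requires a fat or sugar nutrient, "
                f"got {self.nutrient!r}"
            )
        if self.per == "pct_of_total_fat" and self.nutrient not in _FAT_NUTRIENTS:
            raise CriteriaError(
                f"pct_of_total_fat denominator requires a fat nutrient, "
                f"got {self.nutrient!r}"
            )


@dataclass(frozen=True)
class CategoryRule:
    category: str
    eligible: bool = True
    thresholds: tuple[Threshold, ...] = ()

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for t in self.thresholds:
            key = (t.nutrient, t.per)
            if key in seen:
                raise CriteriaError(
                    f"category {self.category!r} has more than one threshold "
                    f"for ({t.nutrient}, {t.per})"
                )
            seen.add(key)


@dataclass(frozen=True)
class CriteriaSet:
    name: str
    rules: Mapping[str, CategoryRule]

    def __post_init__(self) -> None:
        for cat, rule in self.rules.items():
            if rule.category != cat:
                raise CriteriaError(
                    f"rule keyed {cat!r} carries category {rule.category!r}"
                )

    @property
    def category_count(self) -> int:
        return len(self.rules)

    def rule_for(self, category: str) -> CategoryRule:
        try:
            return self.rules[category]
        except KeyError:
            raise CriteriaError(
                f"category {category!r} is not covered by criteria set {self.name!r}"
            ) from None

    def ineligible_categories(self) -> set[str]:
        return {c for c, r in self.rules.items() if not r.eligible}


@dataclass(frozen=True)
class ThresholdFailure:
    nutrient: str
    per: str
    observed: float | None  # None when the threshold could not be evaluated
    limit: float
    reason: str = ""


@dataclass(frozen=True)
class ComplianceResult:
    food_id: str
    complies: bool
    failed_thresholds: tuple[ThresholdFailure, ...] = ()
    ineligible_category: bool = False


def criteria_from_dict(config: Mapping) -> CriteriaSet:
    """Build a validated :class:`CriteriaSet` from a parsed config mapping."""
    if "name" not in config or "categories" not in config:
        raise CriteriaError("criteria config requires keys 'name' and 'categories'")
    rules: dict[str, CategoryRule] = {}
    for i, entry in enumerate(config["categories"]):
        cat = entry.get("category")
        if not cat:
            raise CriteriaError(f"categories[{i}]: missing 'category'")
        if cat in rules:
            raise CriteriaError(f"duplicate category {cat!r} in criteria config")
        thresholds = []
        for j, t in enumerate(entry.get("thresholds") or []):
            try:
                thresholds.append(
                    Threshold(
                        nutrient=t["nutrient"],
                        cmp=t.get("cmp", "le"),
                        limit=float(t["limit"]),
                        per=t.get("per", "per_100_basis"),
                    )
                )
            except (KeyError, CriteriaError) as exc:
                raise CriteriaError(
                    f"categories[{i}] ({cat!r}) thresholds[{j}]: {exc}"
                ) from None
        rules[cat] = CategoryRule(
            category=cat,
            eligible=bool(entry.get("eligible", True)),
            thresholds=tuple(thresholds),
        )
    return CriteriaSet(name=str(config["name"]), rules=rules)


def load_criteria(path) -> CriteriaSet:
    """Load a YAML/JSON criteria config into a :class:`CriteriaSet`."""
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise CriteriaError(f"criteria config {path} did not parse to a mapping")
    return criteria_from_dict(config)


def criteria_to_dict(criteria: CriteriaSet) -> dict:
    return {
        "name": criteria.name,
        "categories": [
            {
                "category": r.category,
                "eligible": r.eligible,
                "thresholds": [
                    {"nutrient": t.nutrient, "cmp": t.cmp, "limit": t.limit, "per": t.per}
                    for t in r.thresholds
                ],
            }
            for r in criteria.rules.values()
        ],
    }


def write_criteria(criteria: CriteriaSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(criteria_to_dict(criteria), fh, sort_keys=False)


def evaluate_threshold(food: FoodItem, threshold: Threshold) -> tuple[float | None, bool]:
    """Evaluate one threshold against a food.

    Returns ``(observed, passes)``.  ``observed`` is the value on the
    threshold's denominator, or ``None`` when it cannot be computed, in which
    case ``passes`` is ``False`` (conservative fail, logged).
    """
    value = food.profile.get(threshold.nutrient)
    if value is None:
        logger.debug(
            "food %s: %s missing, conservative fail for %s threshold",
            food.food_id,
            threshold.nutrient,
            threshold.per,
        )
        return None, False

    if threshold.per == "per_100_basis":
        observed = value
    elif threshold.per == "per_serving":
        if food.serving_size is None:
            logger.debug(
                "food %s: per_serving threshold without serving_size, conservative fail",
                food.food_id,
            )
            return None, False
        observed = value * food.serving_size / 100.0
    elif threshold.per == "pct_of_energy":
        energy = food.profile.energy
        if not energy:  # missing or zero
            logger.debug(
                "food %s: pct_of_energy with missing/zero energy, conservative fail",
                food.food_id,
            )
            return None, False
        observed = 100.0 * ENERGY_FACTORS[threshold.nutrient] * value / energy
    elif threshold.per == "pct_of_total_fat":
        total_fat = food.profile.total_fat
        if not total_fat:
            logger.debug(
                "food %s: pct_of_total_fat with missing/zero total fat, conservative fail",
                food.food_id,
            )
            return None, False
        observed = 100.0 * value / total_fat
    else:  # pragma: no cover - rejected at Threshold construction
        raise CriteriaError(f"unknown denominator {threshold.per!r}")

    passes = observed <= threshold.limit if threshold.cmp == "le" else observed >= threshold.limit
    return observed, passes


def classify_food(food: FoodItem, criteria: CriteriaSet) -> ComplianceResult:
    """Classify one food; all failing thresholds are enumerated, not just the first."""
    rule = criteria.rule_for(food.category)
    failures = []
    for t in rule.thresholds:
        observed, passes = evaluate_threshold(food, t)
        if not passes:
            reason = "" if observed is not None else "not evaluable (missing data)"
            failures.append(
                ThresholdFailure(
                    nutrient=t.nutrient,
                    per=t.per,
                    observed=observed,
                    limit=t.limit,
                    reason=reason,
                )
            )
    complies = rule.eligible and not failures
    return ComplianceResult(
        food_id=food.food_id,
        complies=complies,
        failed_thresholds=tuple(failures),
        ineligible_category=not rule.eligible,
    )


@dataclass(frozen=True)
class ComplianceSummary:
    """Classification counts over the processed foods of a database."""

    n_processed: int
    n_compliant: int
    n_noncompliant: int
    n_replaceable: int  # non-compliant foods with >= 1 compliant same-category candidate
    results: Mapping[str, ComplianceResult] = field(repr=False, default_factory=dict)

    @property
    def frac_compliant(self) -> float | None:
        return self.n_compliant / self.n_processed if self.n_processed else None

    @property
    def frac_noncompliant(self) -> float | None:
        return self.n_noncompliant / self.n_processed if self.n_processed else None

    @property
    def frac_replaceable(self) -> float | None:
        """Share of *non-compliant* foods that could be replaced."""
        return self.n_replaceable / self.n_noncompliant if self.n_noncompliant else None


def classify_database(db: FoodDatabase, criteria: CriteriaSet) -> ComplianceSummary:
    """Classify every processed food in ``db`` and summarise the partition.

    Compliant and non-compliant counts partition the processed foods exactly;
    ``n_replaceable`` counts the non-compliant foods whose category contains
    at least one compliant processed food (i.e., a replacement candidate).
    """
    results: dict[str, ComplianceResult] = {}
    compliant_by_cat: dict[str, int] = {}
    for food in db.processed_foods():
        res = classify_food(food, criteria)
        results[food.food_id] = res
        if res.complies:
            compliant_by_cat[food.category] = compliant_by_cat.get(food.category, 0) + 1
    n_processed = len(results)
    n_compliant = sum(r.complies for r in results.values())
    n_replaceable = sum(
        1
        for fid, r in results.items()
        if not r.complies and compliant_by_cat.get(db[fid].category, 0) > 0
    )
    return ComplianceSummary(
        n_processed=n_processed,
        n_compliant=n_compliant,
        n_noncompliant=n_processed - n_compliant,
        n_replaceable=n_replaceable,
        results=results,
    )


def relax_criteria(criteria: CriteriaSet, factor: float, name: str | None = None) -> CriteriaSet:
    """Return a weakly looser criteria set: <= limits scaled up and >= limits
    scaled down by ``factor`` (> 1).  Useful for dominance checks and for
    constructing a permissive comparison set."""
    if factor < 1:
        raise CriteriaError("relaxation factor must be >= 1")
    rules = {}
    for cat, rule in criteria.rules.items():
        thresholds = tuple(
            replace(t, limit=t.limit * factor if t.cmp == "le" else t.limit / factor)
            for t in rule.thresholds
        )
        rules[cat] = CategoryRule(category=cat, eligible=rule.eligible, thresholds=thresholds)
    return CriteriaSet(name=name or f"{criteria.name}-relaxed", rules=rules)


class ComplianceClassifier(BaseEstimator):
    """Scikit-learn-style classifier of foods against a nutrient-profiling
    criteria set.

    The "model" is fully specified by the criteria set; ``fit`` validates
    that every processed food's category is covered and caches per-food
    results.  ``predict`` returns compliance as a boolean array.

    Parameters
    ----------
    criteria : CriteriaSet
        The active criteria set.

    Attributes
    ----------
    results_ : dict[str, ComplianceResult]
        Per-food classification of the fitted database's processed foods.
    summary_ : ComplianceSummary
        Counts and fractions over the processed foods.
    """

    def __init__(self, criteria: CriteriaSet | None = None):
        self.criteria = criteria

    def fit(self, X: FoodDatabase, y=None) -> "ComplianceClassifier":
        if self.criteria is None:
            raise CriteriaError("ComplianceClassifier requires a criteria set")
        if len(X) == 0:
            raise CriteriaError("cannot classify an empty food database")
        missing = {
            f.category for f in X.processed_foods() if f.category not in self.criteria.rules
        }
        if missing:
            raise CriteriaError(
                f"categories {sorted(missing)} are not covered by criteria "
                f"set {self.criteria.name!r}"
            )
        self.summary_ = classify_database(X, self.criteria)
        self.results_ = dict(self.summary_.results)
        return self

    def predict(self, X: FoodDatabase | Iterable[FoodItem]) -> np.ndarray:
        """Boolean compliance for each food in ``X`` (processed or not)."""
        if self.criteria is None:
            raise CriteriaError("ComplianceClassifier requires a criteria set")
        return np.array([classify_food(f, self.criteria).complies for f in X], dtype=bool)

    def compliance_frame(self) -> pd.DataFrame:
        """Fitted per-food results as a tidy frame."""
        if not hasattr(self, "results_"):
            raise CriteriaError("classifier is not fitted")
        return pd.DataFrame(
            [
                {
                    "food_id": r.food_id,
                    "complies": r.complies,
                    "ineligible_category": r.ineligible_category,
                    "n_failed_thresholds": len(r.failed_thresholds),
                    "failed": ";".join(
                        f"{f.nutrient}[{f.per}]" for f in r.failed_thresholds
                    ),
                }
                for r in self.results_.values()
            ]
        )


__all__ = [
    "KNOWN_NUTRIENTS",
    "KNOWN_DENOMINATORS",
    "ENERGY_FACTORS",
    "Threshold",
    "CategoryRule",
    "CriteriaSet",
    "ThresholdFailure",
    "ComplianceResult",
    "ComplianceSummary",
    "criteria_from_dict",
    "criteria_to_dict",
    "load_criteria",
    "write_criteria",
    "evaluate_threshold",
    "classify_food",
    "classify_database",
    "relax_criteria",
    "ComplianceClassifier",
]
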