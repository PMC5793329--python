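"""Non-compliant -> compliant food replacement and the three intake scenarios.

Scenario 1 is the observed diet.  Scenario 2 replaces each non-compliant
processed food (when a compliant processed food of the same category exists)
while keeping the consumed amount.  Scenario 3 additionally multiplies the
amount by the ratio of energy densities, original / replacement, so the
replaced entry supplies exactly the original energy - except for categories
exempt from rescaling (sugar-sweetened beverages, bakery, dairy in the
motivating analysis), which keep scenario-2 amounts because rescaling them
would imply implausibly large consumed volumes.

The replacement map is global (one replacement per food, applied to every
recall entry of that food) and deterministic: the candidate with the nearest
energy density is chosen, ties broken by lexicographic ``food_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .criteria import CriteriaSet, classify_database
from .errors import DataError, PipelineError
from .io import FoodDatabase, FoodItem

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Replacement:
    replacement_id: str
    #: ratio of energy densities original/replacement; multiplies the amount
    #: under scenario 3 so the entry's energy is conserved
    correction_factor: float


@dataclass(frozen=True)
class ReplacementMap:
    criteria_name: str
    entries: Mapping[str, Replacement]
    unreplaced: frozenset[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"original_id": k, "replacement_id": v.replacement_id, "factor": v.correction_factor}
            for k, v in sorted(self.entries.items())
        ]
        rows += [
            {"original_id": k, "replacement_id": "", "factor": float("nan")}
            for k in sorted(self.unreplaced)
        ]
        return pd.DataFrame(rows, columns=["original_id", "replacement_id", "factor"])


@dataclass(frozen=True)
class ScenarioSpec:
    """Which scenario to run and with which category sets.

    ``exempt_categories`` is only meaningful for scenario 3 (entries in those
    categories are replaced but not rescaled).  ``restrict_to_categories``
    limits replacement to entries whose food's category is in the set; all
    other entries pass through untouched.
    """

    scenario: int
    criteria: str = ""
    exempt_categories: frozenset[str] = field(default_factory=frozenset)
    restrict_to_categories: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3):
            raise PipelineError(f"scenario must be 1, 2 or 3, got {self.scenario}")


def nearest_energy_density(original: FoodItem, candidates: list[FoodItem]) -> FoodItem:
    """Default candidate rule: minimise |energy_density(candidate) - original|,
    lexicographic ``food_id`` tie-break.  Candidates or originals without an
    energy value sort by id only (distance treated as 0)."""
    ed0 = original.energy_density

    def key(c: FoodItem) -> tuple[float, str]:
        ed = c.energy_density
        dist = abs(ed - ed0) if (ed is not None and ed0 is not None) else 0.0
        return (dist, c.food_id)

    return min(candidates, key=key)


CANDIDATE_RULES: dict[str, Callable[[FoodItem, list[FoodItem]], FoodItem]] = {
    "nearest_energy_density": nearest_energy_density,
}


def _correction_factor(original: FoodItem, replacement: FoodItem) -> float:
    ed0, ed1 = original.energy_density, replacement.energy_density
    if not ed0 or not ed1:  # zero or missing energy: factor undefined
        logger.warning(
            "correction factor undefined for %s -> %s (zero/missing energy); using 1",
            original.food_id,
            replacement.food_id,
        )
        return 1.0
    return ed0 / ed1


def build_replacement_map(
    db: FoodDatabase,
    criteria: CriteriaSet,
    candidate_rule: str | Callable[[FoodItem, list[FoodItem]], FoodItem] = "nearest_energy_density",
) -> ReplacementMap:
    """Map every non-compliant processed food to its compliant same-category
    replacement, or record it as unreplaced when no candidate exists."""
    rule = CANDIDATE_RULES[candidate_rule] if isinstance(candidate_rule, str) else candidate_rule
    summary = classify_database(db, criteria)
    compliant_by_cat: dict[str, list[FoodItem]] = {}
    for fid, res in summary.results.items():
        if res.complies:
            food = db[fid]
            compliant_by_cat.setdefault(food.category, []).append(food)

    entries: dict[str, Replacement] = {}
    unreplaced: set[str] = set()
    for fid, res in summary.results.items():
        if res.complies:
            continue
        food = db[fid]
        candidates = compliant_by_cat.get(food.category, [])
        if not candidates:
            unreplaced.add(fid)
            continue
        chosen = rule(food, candidates)
        entries[fid] = Replacement(
            replacement_id=chosen.food_id,
            correction_factor=_correction_factor(food, chosen),
        )
    logger.info(
        "replacement map under %s: %d replaced, %d unreplaced of %d non-compliant",
        criteria.name,
        len(entries),
        len(unreplaced),
        summary.n_noncompliant,
    )
    return ReplacementMap(
        criteria_name=criteria.name, entries=entries, unreplaced=frozenset(unreplaced)
    )


def apply_scenario(
    recalls: pd.DataFrame,
    db: FoodDatabase,
    replacement_map: ReplacementMap,
    spec: ScenarioSpec,
) -> pd.DataFrame:
    """Return the recall table under a scenario.

    Scenario 1 returns a copy of the input.  Scenario 2 swaps the food id and
    keeps the amount.  Scenario 3 swaps and multiplies the amount by the
    correction factor, except for entries whose (original) category is in
    ``spec.exempt_categories``.  Unreplaced foods always pass through.
    """
    unknown = sorted(set(recalls["food_id"]) - set(db.food_ids))
    if unknown:
        raise DataError(f"recall entries reference foods absent from the database: {unknown}")

    out = recalls.copy()
    if spec.scenario == 1:
        return out

    restrict = spec.restrict_to_categories
    new_ids = out["food_id"].to_list()
    new_amounts = out["amount"].to_list()
    for i, (fid, amount) in enumerate(zip(new_ids, new_amounts)):
        rep = replacement_map.entries.get(fid)
        if rep is None:
            continue
        category = db[fid].category
        if restrict is not None and category not in restrict:
            continue
        new_ids[i] = rep.replacement_id
        if spec.scenario == 3 and category not in spec.exempt_categories:
            new_amounts[i] = amount * rep.correction_factor
    out["food_id"] = new_ids
    out["amount"] = new_amounts
    return out


def run_restricted_replacement(
    recalls: pd.DataFrame,
    db: FoodDatabase,
    replacement_map: ReplacementMap,
    categories: Iterable[str],
    scenario: int = 2,
    exempt_categories: Iterable[str] = (),
) -> pd.DataFrame:
    """Replacement limited to the given categories; entries outside them are
    returned unchanged.  Unknown category labels raise."""
    cats = frozenset(categories)
    known = db.categories()
    unknown = sorted(cats - known)
    if unknown:
        raise DataError(f"unknown category labels: {unknown}")
    spec = ScenarioSpec(
        scenario=scenario,
        exempt_categories=frozenset(exempt_categories),
        restrict_to_categories=cats,
    )
    return apply_scenario(recalls, db, replacement_map, spec)


class ScenarioReplacer(BaseEstimator, TransformerMixin):
    """Scikit-learn-style transformer running a replacement scenario.

    ``fit`` classifies the food database under the criteria set and builds
    the replacement map; ``transform`` rewrites a recall table under the
    configured scenario.

    Parameters
    ----------
    criteria : CriteriaSet
    scenario : int
        1 (identity), 2 (swap, keep amounts) or 3 (swap and rescale by the
        energy-density ratio).
    exempt_categories : iterable of str
        Categories replaced but never rescaled under scenario 3.
    restrict_to_categories : iterable of str or None
        If set, only entries in these categories are eligible for replacement.
    candidate_rule : str
        Key into :data:`CANDIDATE_RULES`.

    Attributes
    ----------
    replacement_map_ : ReplacementMap
    db_ : FoodDatabase
    """

    def __init__(
        self,
        criteria: CriteriaSet | None = None,
        scenario: int = 3,
        exempt_categories: Iterable[str] = (),
        restrict_to_categories: Iterable[str] | None = None,
        candidate_rule: str = "nearest_energy_density",
    ):
        self.criteria = criteria
        self.scenario = scenario
        self.exempt_categories = exempt_categories
        self.restrict_to_categories = restrict_to_categories
        self.candidate_rule = candidate_rule

    def _spec(self) -> ScenarioSpec:
        return ScenarioSpec(
            scenario=self.scenario,
            criteria=self.criteria.name if self.criteria else "",
            exempt_categories=frozenset(self.exempt_categories),
            restrict_to_categories=(
                frozenset(self.restrict_to_categories)
                if self.restrict_to_categories is not None
                else None
            ),
        )

    def fit(self, X: FoodDatabase, y=None) -> "ScenarioReplacer":
        if self.criteria is None:
            raise PipelineError("ScenarioReplacer requires a criteria set")
        self._spec()  # validates scenario number
        self.db_ = X
        self.replacement_map_ = build_replacement_map(X, self.criteria, self.candidate_rule)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "replacement_map_"):
            raise PipelineError("ScenarioReplacer is not fitted")
        return apply_scenario(X, self.db_, self.replacement_map_, self._spec())


__all__ = [
    "Replacement",
    "ReplacementMap",
    "ScenarioSpec",
    "CANDIDATE_RULES",
    "nearest_energy_density",
    "build_replacement_map",
    "apply_scenario",
    "run_restricted_replacement",
    "ScenarioReplacer",
]
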