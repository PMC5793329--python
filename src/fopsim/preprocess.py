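"""Per-person intake aggregation and participant exclusion filters.

Aggregation turns (person, food, amount) recall entries into daily intake
vectors: for each nutrient, sum over entries of ``amount/100 x per-100
value``.  Grams and millilitres are treated as interchangeable per-100 basis
units (unit density), matching how per-100 g / per-100 mL criteria are
written.

Exclusion applies, in a fixed documented order, the filters used for adult
24HR analyses: age outside 20-59 years, pregnancy or lactation, aberrant BMI
(< 10 or > 58 kg/m2), records with missing age or BMI, and finally a single
pass removing persons whose daily energy lies outside mean +/- 3 SD of the
energy of the pool surviving the earlier filters (unweighted moments).  A
person failing several rules is counted once, under the first failing rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError
from .io import FoodDatabase, NUTRIENT_COLUMNS

logger = logging.getLogger(__name__)

INTAKE_NUTRIENTS: tuple[str, ...] = tuple(NUTRIENT_COLUMNS)

EXCLUSION_REASONS = (
    "age_out_of_range",
    "pregnant_or_lactating",
    "bmi_aberrant",
    "missing_data",
    "energy_outlier",
)


@dataclass
class ExclusionAudit:
    """Counts per exclusion reason; conserves ``initial_n``."""

    initial_n: int
    counts: dict[str, int] = field(default_factory=dict)
    excluded_ids: dict[str, list[str]] = field(default_factory=dict)
    energy_mean: float | None = None
    energy_sd: float | None = None

    @property
    def final_n(self) -> int:
        return self.initial_n - sum(self.counts.values())

    def all_excluded_ids(self) -> set[str]:
        return {pid for ids in self.excluded_ids.values() for pid in ids}

    def to_dict(self) -> dict:
        return {
            "initial_n": self.initial_n,
            "final_n": self.final_n,
            "counts": dict(self.counts),
            "energy_mean": self.energy_mean,
            "energy_sd": self.energy_sd,
        }


def aggregate_intake(recalls: pd.DataFrame, db: FoodDatabase) -> pd.DataFrame:
    """Aggregate recall entries into per-person daily intake vectors.

    Returns a frame indexed by ``person_id`` with one column per nutrient
    (canonical names).  Nutrients missing from a food's composition record
    contribute nothing to the sum.  Persons present in ``recalls`` with zero
    entries cannot occur (a row *is* an entry); callers wanting zero vectors
    for recall-free persons should reindex the result.
    """
    if recalls.empty:
        return pd.DataFrame(columns=list(INTAKE_NUTRIENTS)).rename_axis("person_id")
    unknown = sorted(set(recalls["food_id"]) - set(db.food_ids))
    if unknown:
        raise DataError(f"recall entries reference unknown food ids: {unknown}")

    per100 = pd.DataFrame(
        {
            "food_id": [f.food_id for f in db],
            **{
                nutrient: [f.profile.get(nutrient) for f in db]
                for nutrient in INTAKE_NUTRIENTS
            },
        }
    ).set_index("food_id")
    per100 = per100.astype(float)  # None -> NaN
    merged = recalls.merge(per100, left_on="food_id", right_index=True, how="left")
    scale = merged["amount"].to_numpy() / 100.0
    for nutrient in INTAKE_NUTRIENTS:
        merged[nutrient] = merged[nutrient].to_numpy() * scale
    out = merged.groupby("person_id")[list(INTAKE_NUTRIENTS)].sum(min_count=0)
    return out.fillna(0.0)


def apply_exclusions(
    participants: pd.DataFrame,
    intakes: pd.DataFrame,
    age_range: tuple[float, float] = (20.0, 59.0),
    bmi_range: tuple[float, float] = (10.0, 58.0),
    energy_sd_limit: float = 3.0,
) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Apply the participant exclusion filters and return (retained, audit).

    Persons absent from ``intakes`` are treated as having zero energy (an
    empty recall).  The energy filter is applied exactly once, using the
    unweighted mean and SD over the pool surviving the earlier filters.
    """
    p = participants.set_index("person_id", drop=False)
    if p.index.has_duplicates:
        raise DataError("duplicate person_id in participant table")
    energy = intakes["energy"].reindex(p.index).fillna(0.0) if len(intakes) else pd.Series(0.0, index=p.index)

    audit = ExclusionAudit(initial_n=len(p), counts={r: 0 for r in EXCLUSION_REASONS})
    audit.excluded_ids = {r: [] for r in EXCLUSION_REASONS}

    def exclude(pid: str, reason: str) -> None:
        audit.counts[reason] += 1
        audit.excluded_ids[reason].append(pid)

    pool: list[str] = []
    for pid, row in p.iterrows():
        age, bmi = row["age"], row["bmi"]
        if pd.notna(age) and not (age_range[0] <= age <= age_range[1]):
            exclude(pid, "age_out_of_range")
        elif bool(row["pregnant_or_lactating"]):
            exclude(pid, "pregnant_or_lactating")
        elif pd.notna(bmi) and not (bmi_range[0] <= bmi <= bmi_range[1]):
            exclude(pid, "bmi_aberrant")
        elif pd.isna(age) or pd.isna(bmi):
            exclude(pid, "missing_data")
        else:
            pool.append(pid)

    if pool:
        e = energy.loc[pool]
        mean, sd = float(e.mean()), float(e.std(ddof=1)) if len(e) > 1 else 0.0
        audit.energy_mean, audit.energy_sd = mean, sd
        lo, hi = mean - energy_sd_limit * sd, mean + energy_sd_limit * sd
        retained_ids = []
        for pid in pool:
            if lo <= energy.loc[pid] <= hi:
                retained_ids.append(pid)
            else:
                exclude(pid, "energy_outlier")
    else:
        retained_ids = []

    retained = p.loc[retained_ids].reset_index(drop=True)
    assert len(retained) + sum(audit.counts.values()) == audit.initial_n
    logger.info(
        "exclusions: %d -> %d (%s)",
        audit.initial_n,
        audit.final_n,
        ", ".join(f"{k}={v}" for k, v in audit.counts.items() if v),
    )
    return retained, audit


__all__ = [
    "INTAKE_NUTRIENTS",
    "EXCLUSION_REASONS",
    "ExclusionAudit",
    "aggregate_intake",
    "apply_exclusions",
]
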