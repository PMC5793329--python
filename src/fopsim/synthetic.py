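"""Synthetic dietary surveys with known ground truth.

The generator emulates the structure of a national 24HR dietary sub-sample:
a food database of ~19 categories mixing compliant and non-compliant
processed foods, person-day recalls whose energy is roughly log-normal
around a 1900 kcal/day median, survey weights with strata/PSU structure,
and planted exclusion cases (pregnancy, aberrant BMI, extreme energy).

Ground truth is exact by construction:

* within a category every food shares a per-kcal nutrient anchor; compliant
  foods carry the anchor scaled by ``1 - r`` (the planted reduction), so
  under the energy-conserving scenario 3 every replaced entry's nutrient
  content shrinks by exactly ``r`` up to a small symmetric log-normal jitter;
* the criteria set is generated with each category's threshold at the
  geometric midpoint between the compliant and non-compliant anchors, and
  compliance labels are enforced by rejection sampling against the actual
  classification engine, so planted labels are exact;
* every recall entry supplies a fixed energy (an equal split of the
  category's share), so a category's expected per-kcal nutrient density is
  ``a_ck (q_c + (1-q_c)(1-r_ck))`` before replacement (non-compliant foods,
  drawn with probability ``q_c``, sit at the anchor ``a_ck``; compliant ones
  at ``a_ck (1-r_ck)``) and exactly ``a_ck (1-r_ck)`` after scenario-3
  replacement of a replaceable category; the expected population percent
  change is the share-weighted ratio of these densities.

Natural energy draws are truncated at ``energy_trunc_z`` log-SDs so that the
planted high-energy outliers are the only records outside the mean +/- 3 SD
exclusion band (exact planted-exclusion recovery).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .criteria import CategoryRule, CriteriaSet, Threshold, classify_food
from .errors import DataError
from .io import FoodDatabase, FoodItem, NutrientProfile
from .preprocess import INTAKE_NUTRIENTS

logger = logging.getLogger(__name__)

#: nutrient -> jitter group (one log-normal draw per group per food keeps the
#: composition invariants added<=total sugar and sat+trans<=total fat intact)
_JITTER_GROUPS = {
    "saturated_fat": "fat",
    "trans_fat": "fat",
    "total_fat": "fat",
    "total_sugar": "sugar",
    "added_sugar": "sugar",
    "sodium": "sodium",
    "fiber": "fiber",
}


@dataclass(frozen=True)
class CategorySpec:
    """One category of the synthetic food supply.

    ``anchors`` holds per-kcal nutrient content (g/kcal, sodium in mg/kcal);
    ``reductions`` the planted relative reduction of compliant vs
    non-compliant foods (negative values mean compliant foods carry *more*,
    used for fiber).  ``share`` is the category's share of every person's
    daily energy.
    """

    name: str
    processed: bool
    share: float
    energy_density: float  # kcal per 100 basis units
    basis: str = "per_100_g"
    anchors: dict[str, float] = field(default_factory=dict)
    reductions: dict[str, float] = field(default_factory=dict)


def default_categories() -> list[CategorySpec]:
    """A 19-category food supply loosely shaped like a Mexican adult diet:
    16 processed categories (sugar-heavy beverages, bakery, dairy, snacks,
    processed meats, ...) plus home-prepared staples, fruits/vegetables and
    fresh animal foods."""
    c = CategorySpec
    return [
        c("soft drinks", True, 0.09, 44, "per_100_mL",
          {"total_sugar": 0.25, "added_sugar": 0.24, "sodium": 0.2},
          {"total_sugar": 0.92, "added_sugar": 0.92}),
        c("fruit and vegetable juices", True, 0.03, 45, "per_100_mL",
          {"total_sugar": 0.24, "added_sugar": 0.12, "sodium": 0.1, "fiber": 0.002},
          {"total_sugar": 0.5, "added_sugar": 0.5}),
        c("dairy drinks", True, 0.04, 70, "per_100_mL",
          {"saturated_fat": 0.022, "total_fat": 0.05, "total_sugar": 0.13,
           "added_sugar": 0.07, "sodium": 0.6},
          {"saturated_fat": 0.3, "total_fat": 0.3, "total_sugar": 0.4, "added_sugar": 0.4}),
        c("yogurt and fermented milks", True, 0.02, 90, "per_100_g",
          {"saturated_fat": 0.018, "total_fat": 0.04, "total_sugar": 0.14,
           "added_sugar": 0.08, "sodium": 0.5},
          {"saturated_fat": 0.3, "total_fat": 0.3, "total_sugar": 0.4, "added_sugar": 0.4}),
        c("cheese", True, 0.03, 350, "per_100_g",
          {"saturated_fat": 0.05, "total_fat": 0.09, "sodium": 1.8},
          {"saturated_fat": 0.25, "total_fat": 0.25, "sodium": 0.3}),
        c("breakfast cereals", True, 0.03, 380, "per_100_g",
          {"total_sugar": 0.06, "added_sugar": 0.05, "sodium": 1.2, "fiber": 0.01},
          {"total_sugar": 0.5, "added_sugar": 0.5, "sodium": 0.3, "fiber": -0.8}),
        c("bread and tortillas", True, 0.06, 280, "per_100_g",
          {"total_sugar": 0.02, "added_sugar": 0.01, "sodium": 1.7, "fiber": 0.012},
          {"sodium": 0.3, "fiber": -0.8}),
        c("bakery products", True, 0.05, 400, "per_100_g",
          {"saturated_fat": 0.012, "trans_fat": 0.0009, "total_fat": 0.04,
           "total_sugar": 0.06, "added_sugar": 0.05, "sodium": 0.9, "fiber": 0.005},
          {"saturated_fat": 0.35, "trans_fat": 0.6, "total_fat": 0.35,
           "total_sugar": 0.4, "added_sugar": 0.4}),
        c("cookies and biscuits", True, 0.03, 480, "per_100_g",
          {"saturated_fat": 0.011, "trans_fat": 0.0008, "total_fat": 0.045,
           "total_sugar": 0.07, "added_sugar": 0.06, "sodium": 0.7},
          {"saturated_fat": 0.35, "trans_fat": 0.6, "total_fat": 0.35,
           "total_sugar": 0.4, "added_sugar": 0.4}),
        c("salty snacks", True, 0.03, 520, "per_100_g",
          {"saturated_fat": 0.009, "trans_fat": 0.0006, "total_fat": 0.055,
           "sodium": 1.8, "fiber": 0.005},
          {"saturated_fat": 0.3, "trans_fat": 0.6, "total_fat": 0.3, "sodium": 0.35}),
        c("processed meats", True, 0.04, 250, "per_100_g",
          {"saturated_fat": 0.013, "trans_fat": 0.0004, "total_fat": 0.05, "sodium": 3.6},
          {"saturated_fat": 0.3, "trans_fat": 0.6, "total_fat": 0.3, "sodium": 0.35}),
        c("ready meals and soups", True, 0.05, 180, "per_100_g",
          {"saturated_fat": 0.009, "total_fat": 0.035, "sodium": 2.8, "fiber": 0.006},
          {"saturated_fat": 0.25, "total_fat": 0.25, "sodium": 0.35}),
        c("sauces and dressings", True, 0.02, 250, "per_100_g",
          {"total_sugar": 0.05, "added_sugar": 0.04, "sodium": 3.5, "total_fat": 0.04},
          {"total_sugar": 0.3, "added_sugar": 0.3, "sodium": 0.35}),
        c("cereal bars", True, 0.01, 447, "per_100_g",
          {"saturated_fat": 0.008, "total_fat": 0.02, "total_sugar": 0.07,
           "added_sugar": 0.06, "fiber": 0.008},
          {"saturated_fat": 0.3, "total_fat": 0.3, "total_sugar": 0.4,
           "added_sugar": 0.4, "fiber": -0.5}),
        c("candy and confectionery", True, 0.01, 390, "per_100_g",
          {"total_sugar": 0.18, "added_sugar": 0.17},
          {"total_sugar": 0.5, "added_sugar": 0.5}),
        c("chocolate products", True, 0.01, 530, "per_100_g",
          {"saturated_fat": 0.015, "total_fat": 0.055, "total_sugar": 0.10,
           "added_sugar": 0.09},
          {"saturated_fat": 0.3, "total_fat": 0.3, "total_sugar": 0.4, "added_sugar": 0.4}),
        c("staples", False, 0.30, 150, "per_100_g",
          {"saturated_fat": 0.005, "total_fat": 0.012, "total_sugar": 0.01,
           "sodium": 0.8, "fiber": 0.018}, {}),
        c("fruits and vegetables", False, 0.10, 50, "per_100_g",
          {"total_sugar": 0.08, "sodium": 0.1, "fiber": 0.04}, {}),
        c("fresh meat eggs fish", False, 0.05, 200, "per_100_g",
          {"saturated_fat": 0.035, "total_fat": 0.09, "sodium": 0.9}, {}),
    ]


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything the generator needs; the seed fully determines the output."""

    seed: int = 0
    n_participants: int = 2000
    foods_per_category: int = 18
    fraction_noncompliant: float = 0.611
    fraction_replaceable: float = 0.8125  # 13 of the 16 processed categories
    categories: tuple[CategorySpec, ...] = field(
        default_factory=lambda: tuple(default_categories())
    )
    criteria_name: str = "synthetic-criteria"
    # intake model
    picks_per_category: int = 4
    energy_median: float = 1900.0
    energy_log_sd: float = 0.43
    energy_trunc_z: float = 1.8
    nutrient_log_sd: float = 0.06
    ed_log_sd: float = 0.12
    # survey design
    n_strata: int = 10
    psus_per_stratum: int = 4
    weight_log_sd: float = 0.5
    # exclusion plants
    n_pregnant: int = 5
    n_bmi_aberrant: int = 2
    n_energy_outliers: int = 3
    outlier_energy: float = 12000.0

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def processed_categories(self) -> list[CategorySpec]:
        return [c for c in self.categories if c.processed]

    def replaceable_names(self) -> set[str]:
        """The first ``round(fraction_replaceable * m)`` processed categories
        (template order) contain compliant candidates; the rest are generated
        all-non-compliant so their foods cannot be replaced."""
        proc = self.processed_categories()
        k = int(round(self.fraction_replaceable * len(proc)))
        return {c.name for c in proc[:k]}

    def n_noncompliant(self, cat: CategorySpec) -> int:
        fpc = self.foods_per_category
        n = int(round(self.fraction_noncompliant * fpc))
        if n <= 0:
            return 0
        if cat.name in self.replaceable_names():
            return min(n, fpc - 1)  # keep >= 1 compliant candidate
        return fpc  # unreplaceable: no compliant candidate at all

    def validate(self) -> None:
        if not 0 <= self.fraction_noncompliant <= 1:
            raise DataError("fraction_noncompliant must be in [0, 1]")
        if not 0 <= self.fraction_replaceable <= 1:
            raise DataError("fraction_replaceable must be in [0, 1]")
        if self.foods_per_category < 2:
            raise DataError("need at least 2 foods per category")
        if self.n_participants < 1:
            raise DataError("need at least one participant")
        shares = sum(c.share for c in self.categories)
        if abs(shares - 1.0) > 1e-6:
            raise DataError(f"category energy shares must sum to 1, got {shares}")
        plants = self.n_pregnant + self.n_bmi_aberrant + self.n_energy_outliers
        if plants > self.n_participants // 4:
            raise DataError("too many planted exclusions for the sample size")
        if self.fraction_replaceable > 0 and self.fraction_noncompliant >= 1:
            raise DataError(
                "infeasible: replaceable categories need at least one compliant food "
                "(fraction_noncompliant must be < 1 when fraction_replaceable > 0)"
            )
        for cat in self.categories:
            for nutrient, r in cat.reductions.items():
                if nutrient not in cat.anchors and r != 0:
                    raise DataError(
                        f"category {cat.name!r} plants a reduction on {nutrient!r} "
                        "without an anchor"
                    )
            if (
                cat.processed
                and self.n_noncompliant(cat) > 0
                and not any(
                    r != 0 for n, r in cat.reductions.items() if n != "total_fat"
                )
            ):
                raise DataError(
                    f"processed category {cat.name!r} needs at least one non-zero "
                    "reduction (a defining nutrient) to separate compliant from "
                    "non-compliant foods"
                )


@dataclass(frozen=True)
class GroundTruth:
    expected_pct_change: dict[str, float]
    excluded_ids: frozenset[str]
    compliance: dict[str, bool]


def expected_change(
    config: GeneratorConfig, restrict_to: set[str] | None = None
) -> dict[str, float]:
    """Closed-form expected percent change of population intake under an
    unexempted scenario-3 replacement, per nutrient (energy included, 0 by
    energy conservation).  ``restrict_to`` limits the replacement to a
    category subset, as in a group-restricted analysis."""
    config.validate()
    replaceable = config.replaceable_names()
    replaced_cats = replaceable if restrict_to is None else replaceable & set(restrict_to)
    out: dict[str, float] = {}
    for nutrient in INTAKE_NUTRIENTS:
        if nutrient == "energy":
            out[nutrient] = 0.0
            continue
        before = after = 0.0
        for c in config.categories:
            a = c.anchors.get(nutrient, 0.0)
            r = c.reductions.get(nutrient, 0.0) if c.processed else 0.0
            if c.processed and c.name in replaceable:
                # category mixes non-compliant (density a, probability q) and
                # compliant (a(1-r)) foods before replacement
                q = config.n_noncompliant(c) / config.foods_per_category
                d1 = a * (q + (1.0 - q) * (1.0 - r))
                d3 = a * (1.0 - r) if c.name in replaced_cats else d1
            else:
                # unreplaceable processed categories are generated all
                # non-compliant (density a); unprocessed foods sit at a too
                d1 = d3 = a
            before += c.share * d1
            after += c.share * d3
        out[nutrient] = 100.0 * (after - before) / before if before else 0.0
    return out


def _criteria_for(config: GeneratorConfig) -> CriteriaSet:
    """Thresholds at the geometric midpoint between the compliant and
    non-compliant per-100 anchors; only nutrients with a planted reduction
    get a threshold (they are the defining nutrients of the category)."""
    rules = {}
    for cat in config.categories:
        if not cat.processed:
            continue
        thresholds = []
        for nutrient, r in sorted(cat.reductions.items()):
            if r == 0 or nutrient == "total_fat":
                continue  # total_fat tracks saturated fat; no separate rule
            anchor_100 = cat.anchors[nutrient] * cat.energy_density
            limit = anchor_100 * float(np.sqrt(1.0 - r))
            cmp = "ge" if r < 0 else "le"
            thresholds.append(Threshold(nutrient=nutrient, cmp=cmp, limit=limit))
        rules[cat.name] = CategoryRule(
            category=cat.name, eligible=True, thresholds=tuple(thresholds)
        )
    return CriteriaSet(name=config.criteria_name, rules=rules)


def _make_food(
    rng: np.random.Generator,
    config: GeneratorConfig,
    cat: CategorySpec,
    food_id: str,
    name: str,
    compliant: bool,
    rule: CategoryRule | None,
) -> FoodItem:
    """Draw one food; rejection-sample the jitters until the engine's
    classification matches the planted label (falls back to the exact anchors,
    which always classify correctly, after 200 tries)."""
    criteria_stub = (
        CriteriaSet(name="stub", rules={cat.name: rule}) if rule is not None else None
    )
    for attempt in range(201):
        if attempt < 200:
            z_ed = rng.normal(0.0, config.ed_log_sd)
            z_grp = {g: rng.normal(0.0, config.nutrient_log_sd) for g in ("fat", "sugar", "sodium", "fiber")}
        else:  # deterministic fallback: anchors sit strictly inside/outside the limits
            z_ed = 0.0
            z_grp = {g: 0.0 for g in ("fat", "sugar", "sodium", "fiber")}
        ed = cat.energy_density * float(np.exp(z_ed))
        values: dict[str, float] = {"energy": ed}
        for nutrient, anchor in cat.anchors.items():
            r = cat.reductions.get(nutrient, 0.0) if compliant else 0.0
            jitter = float(np.exp(z_grp[_JITTER_GROUPS[nutrient]]))
            values[nutrient] = anchor * (1.0 - r) * ed * jitter
        profile = NutrientProfile(**{k: values.get(k) for k in INTAKE_NUTRIENTS})
        food = FoodItem(
            food_id=food_id,
            name=name,
            category=cat.name,
            processed=cat.processed,
            basis=cat.basis,
            serving_size=None,
            profile=profile,
        )
        if criteria_stub is None:
            return food
        if classify_food(food, criteria_stub).complies == compliant:
            return food
    raise AssertionError("rejection sampling fallback failed")  # pragma: no cover


def generate_food_database(
    rng: np.random.Generator, config: GeneratorConfig
) -> tuple[FoodDatabase, CriteriaSet, dict[str, bool]]:
    criteria = _criteria_for(config)
    db = FoodDatabase()
    compliance: dict[str, bool] = {}
    for ci, cat in enumerate(config.categories):
        rule = criteria.rules.get(cat.name)
        n_nc = config.n_noncompliant(cat) if cat.processed else 0
        for fi in range(config.foods_per_category):
            compliant = fi >= n_nc  # first n_nc foods planted non-compliant
            food_id = f"F{ci:02d}{fi:02d}"
            food = _make_food(
                rng, config, cat, food_id,
                name=f"{cat.name} item {fi}",
                compliant=compliant,
                rule=rule if cat.processed else None,
            )
            db.add(food)
            if cat.processed:
                compliance[food_id] = compliant
    return db, criteria, compliance


def generate_participants(
    rng: np.random.Generator, config: GeneratorConfig
) -> tuple[pd.DataFrame, np.ndarray, frozenset[str]]:
    """Participant table, per-person daily energy, and planted-excluded ids."""
    n = config.n_participants
    person_ids = [f"P{i:05d}" for i in range(n)]

    # truncated log-normal energy: no natural draw can cross the +/-3 SD band
    z = rng.normal(0.0, 1.0, size=n)
    while True:
        bad = np.abs(z) > config.energy_trunc_z
        if not bad.any():
            break
        z[bad] = rng.normal(0.0, 1.0, size=int(bad.sum()))
    energy = config.energy_median * np.exp(config.energy_log_sd * z)

    weights = np.exp(rng.normal(0.0, config.weight_log_sd, size=n))
    weights *= n / weights.sum()
    strata = rng.integers(0, config.n_strata, size=n)
    psus = rng.integers(0, config.psus_per_stratum, size=n)
    sex = np.where(rng.random(n) < 0.52, "female", "male")
    age = rng.integers(20, 60, size=n).astype(float)
    bmi = np.clip(rng.normal(27.5, 4.5, size=n), 16.0, 45.0)
    region = rng.choice(["north", "center", "south"], size=n, p=[0.20, 0.49, 0.31])
    locality = np.where(rng.random(n) < 0.75, "urban", "rural")
    ses = rng.choice(["low", "middle", "high"], size=n, p=[0.29, 0.30, 0.41])
    pregnant = np.zeros(n, dtype=bool)

    n_plants = config.n_pregnant + config.n_bmi_aberrant + config.n_energy_outliers
    plant_idx = rng.choice(n, size=n_plants, replace=False)
    preg_idx = plant_idx[: config.n_pregnant]
    bmi_idx = plant_idx[config.n_pregnant : config.n_pregnant + config.n_bmi_aberrant]
    energy_idx = plant_idx[config.n_pregnant + config.n_bmi_aberrant :]
    pregnant[preg_idx] = True
    sex[preg_idx] = "female"
    bmi[bmi_idx] = 60.0
    energy[energy_idx] = config.outlier_energy

    participants = pd.DataFrame(
        {
            "person_id": person_ids,
            "weight": weights,
            "stratum": strata,
            "psu": psus,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "region": region,
            "locality": locality,
            "ses": ses,
            "pregnant_or_lactating": pregnant,
        }
    )
    excluded = frozenset(person_ids[i] for i in plant_idx)
    return participants, energy, excluded


def generate_recalls(
    rng: np.random.Generator,
    config: GeneratorConfig,
    db: FoodDatabase,
    person_ids: list[str],
    energy: np.ndarray,
) -> pd.DataFrame:
    """``picks_per_category`` entries per person per category, each a
    uniformly drawn food consumed in the amount supplying an equal split of
    the category's energy share.  Several draws per category keep the
    person-level replacement ratio approximately symmetric, so the weighted
    median change tracks the closed-form mean change."""
    foods_by_cat: dict[str, list[FoodItem]] = {}
    for f in db:
        foods_by_cat.setdefault(f.category, []).append(f)
    rows_person, rows_food, rows_amount = [], [], []
    n = len(person_ids)
    k = config.picks_per_category
    for cat in config.categories:
        foods = foods_by_cat[cat.name]
        picks = rng.integers(0, len(foods), size=(n, k))
        for i, pid in enumerate(person_ids):
            entry_energy = cat.share * energy[i] / k
            for j in range(k):
                food = foods[picks[i, j]]
                amount = 100.0 * entry_energy / food.profile.energy
                rows_person.append(pid)
                rows_food.append(food.food_id)
                rows_amount.append(amount)
    out = pd.DataFrame({"person_id": rows_person, "food_id": rows_food, "amount": rows_amount})
    return out.sort_values(["person_id", "food_id"], kind="stable", ignore_index=True)


def generate_survey(
    config: GeneratorConfig,
) -> tuple[FoodDatabase, CriteriaSet, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a complete survey fixture: food database, criteria set,
    recall table, participant table and the ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    db, criteria, compliance = generate_food_database(rng, config)
    participants, energy, excluded = generate_participants(rng, config)
    recalls = generate_recalls(rng, config, db, list(participants["person_id"]), energy)
    truth = GroundTruth(
        expected_pct_change=expected_change(config),
        excluded_ids=excluded,
        compliance=compliance,
    )
    logger.info(
        "generated survey: %d foods, %d categories, %d persons, %d recall entries",
        len(db), config.n_categories, config.n_participants, len(recalls),
    )
    return db, criteria, recalls, participants, truth


def ssb_demo_config(seed: int = 0, n_participants: int = 2000) -> GeneratorConfig:
    """A reduced three-category supply where sugar-sweetened beverages carry
    ~30% of population sugar and replacement strips ~90% of it (9 of 10 SSBs
    are non-compliant, compliant ones keep 1% of the sugar): restricted SSB
    replacement is then expected to cut population sugar by ~27%."""
    cats = (
        CategorySpec("soft drinks", True, 0.15, 44, "per_100_mL",
                     {"total_sugar": 0.24, "added_sugar": 0.23},
                     {"total_sugar": 0.99, "added_sugar": 0.99}),
        CategorySpec("bakery products", True, 0.35, 400, "per_100_g",
                     {"total_sugar": 0.10, "added_sugar": 0.08, "sodium": 1.0},
                     {"total_sugar": 0.5, "added_sugar": 0.5}),
        CategorySpec("staples", False, 0.50, 150, "per_100_g",
                     {"total_sugar": 0.096, "sodium": 0.9, "fiber": 0.02}, {}),
    )
    # SSB sugar share: .15*.24 / (.15*.24 + .35*.10 + .50*.096) = .036/.1186 = 30.4%
    # restricted sugar change (see expected_change): about -28%
    return GeneratorConfig(
        seed=seed,
        n_participants=n_participants,
        categories=cats,
        foods_per_category=10,
        fraction_noncompliant=0.9,
        fraction_replaceable=1.0,
        n_pregnant=0,
        n_bmi_aberrant=0,
        n_energy_outliers=0,
    )


__all__ = [
    "CategorySpec",
    "GeneratorConfig",
    "GroundTruth",
    "default_categories",
    "expected_change",
    "generate_survey",
    "generate_food_database",
    "generate_participants",
    "generate_recalls",
    "ssb_demo_config",
]
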