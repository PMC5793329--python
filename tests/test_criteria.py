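"""Criteria engine: threshold arithmetic, classification, config loading,
and equivalence with an independent brute-force evaluator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fopsim.criteria import (
    CategoryRule,
    ComplianceClassifier,
    CriteriaSet,
    Threshold,
    classify_database,
    classify_food,
    criteria_from_dict,
    evaluate_threshold,
    load_criteria,
    relax_criteria,
)
from fopsim.errors import CriteriaError
from fopsim.io import FoodDatabase

from conftest import make_food

CONFIG_DIR = __import__("pathlib").Path(__import__("fopsim").__file__).parent / "configs"


# ---------------------------------------------------------------- oracle

def brute_force_observed(food, threshold):
    """Re-derive the observed value from raw fields, independently."""
    raw = {
        "energy": food.profile.energy,
        "saturated_fat": food.profile.saturated_fat,
        "trans_fat": food.profile.trans_fat,
        "total_fat": food.profile.total_fat,
        "total_sugar": food.profile.total_sugar,
        "added_sugar": food.profile.added_sugar,
        "sodium": food.profile.sodium,
        "fiber": food.profile.fiber,
    }
    v = raw[threshold.nutrient]
    if v is None:
        return None
    if threshold.per == "per_100_basis":
        return v
    if threshold.per == "per_serving":
        return None if food.serving_size is None else v * food.serving_size / 100
    if threshold.per == "pct_of_energy":
        e = raw["energy"]
        if e is None or e == 0:
            return None
        kcal_per_g = 9 if "fat" in threshold.nutrient else 4
        return 100 * kcal_per_g * v / e
    if threshold.per == "pct_of_total_fat":
        tf = raw["total_fat"]
        if tf is None or tf == 0:
            return None
        return 100 * v / tf
    raise AssertionError(threshold.per)


def brute_force_complies(food, criteria):
    rule = criteria.rules[food.category]
    if not rule.eligible:
        return False
    for t in rule.thresholds:
        obs = brute_force_observed(food, t)
        if obs is None:
            return False
        ok = obs <= t.limit if t.cmp == "le" else obs >= t.limit
        if not ok:
            return False
    return True


def random_fixture(rng):
    """A random small database and a matching random criteria set."""
    n_cats = rng.integers(1, 5)
    cats = [f"cat{j}" for j in range(n_cats)]
    rules = {}
    for cat in cats:
        thresholds = []
        for nutrient, per_options in (
            ("energy", ["per_100_basis", "per_serving"]),
            ("saturated_fat", ["per_100_basis", "pct_of_energy", "pct_of_total_fat"]),
            ("trans_fat", ["per_100_basis", "pct_of_total_fat"]),
            ("added_sugar", ["per_100_basis", "pct_of_energy"]),
            ("total_sugar", ["per_100_basis"]),
            ("sodium", ["per_100_basis", "per_serving"]),
            ("fiber", ["per_100_basis"]),
        ):
            if rng.random() < 0.55:
                continue
            per = per_options[rng.integers(0, len(per_options))]
            cmp = "ge" if nutrient == "fiber" and rng.random() < 0.5 else "le"
            limit = float(np.round(rng.uniform(0, 30 if per != "per_100_basis" else 500), 2))
            thresholds.append(Threshold(nutrient, cmp, limit, per))
        rules[cat] = CategoryRule(cat, eligible=bool(rng.random() < 0.85), thresholds=tuple(thresholds))
    criteria = CriteriaSet(name="random", rules=rules)

    foods = []
    for i in range(int(rng.integers(1, 51))):
        total_sugar = float(rng.uniform(0, 60)) if rng.random() < 0.9 else None
        added = (
            float(rng.uniform(0, total_sugar)) if total_sugar is not None and rng.random() < 0.8 else None
        )
        sat = float(rng.uniform(0, 20)) if rng.random() < 0.9 else None
        trans = float(rng.uniform(0, 2)) if rng.random() < 0.7 else None
        total_fat = (
            float((sat or 0) + (trans or 0) + rng.uniform(0, 20)) if rng.random() < 0.8 else None
        )
        foods.append(
            make_food(
                f"F{i:03d}",
                category=cats[rng.integers(0, n_cats)],
                energy=float(rng.uniform(0, 600)) if rng.random() < 0.95 else None,
                processed=bool(rng.random() < 0.8),
                serving_size=float(rng.uniform(10, 200)) if rng.random() < 0.6 else None,
                saturated_fat=sat,
                trans_fat=trans,
                total_fat=total_fat,
                total_sugar=total_sugar,
                added_sugar=added,
                sodium=float(rng.uniform(0, 2000)) if rng.random() < 0.9 else None,
                fiber=float(rng.uniform(0, 12)) if rng.random() < 0.8 else None,
            )
        )
    return FoodDatabase(foods), criteria


def test_classification_matches_brute_force_on_random_fixtures():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        db, criteria = random_fixture(rng)
        summary = classify_database(db, criteria)
        expected = {f.food_id: brute_force_complies(f, criteria) for f in db.processed_foods()}
        got = {fid: r.complies for fid, r in summary.results.items()}
        assert got == expected
        assert summary.n_compliant + summary.n_noncompliant == summary.n_processed


# ------------------------------------------------------- threshold math

def test_pct_of_energy_saturated_fat():
    food = make_food("F1", energy=450, saturated_fat=10, total_fat=15)
    observed, passes = evaluate_threshold(
        food, Threshold("saturated_fat", "le", 10.0, per="pct_of_energy")
    )
    assert observed == pytest.approx(20.0)
    assert not passes


def test_boundary_is_inclusive():
    food = make_food("F1", saturated_fat=5.0, total_fat=9.0)
    _, passes = evaluate_threshold(food, Threshold("saturated_fat", "le", 5.0))
    assert passes


def test_missing_nutrient_fails_conservatively():
    food = make_food("F1", saturated_fat=1.0, total_fat=2.0)  # no trans fat recorded
    observed, passes = evaluate_threshold(food, Threshold("trans_fat", "le", 1.0))
    assert observed is None and not passes


def test_per_serving_without_serving_size_fails_conservatively():
    food = make_food("F1", energy=400, serving_size=None)
    observed, passes = evaluate_threshold(
        food, Threshold("energy", "le", 170.0, per="per_serving")
    )
    assert observed is None and not passes


def test_zero_energy_pct_denominator_fails_conservatively():
    food = make_food("F1", energy=0.0, saturated_fat=1.0, total_fat=2.0)
    observed, passes = evaluate_threshold(
        food, Threshold("saturated_fat", "le", 10.0, per="pct_of_energy")
    )
    assert observed is None and not passes


# ----------------------------------------------------- classify_food

def test_all_failures_enumerated(bar_criteria):
    food = make_food("F1", energy=400, added_sugar=30, total_sugar=35, sodium=600,
                     saturated_fat=1, total_fat=4)
    res = classify_food(food, bar_criteria)
    assert not res.complies
    assert {(f.nutrient, f.per) for f in res.failed_thresholds} == {
        ("added_sugar", "per_100_basis"),
        ("sodium", "per_100_basis"),
    }


def test_compliant_food_has_empty_failures(bar_criteria):
    food = make_food("F1", energy=350, added_sugar=10, total_sugar=12, sodium=200,
                     saturated_fat=2, total_fat=8)
    res = classify_food(food, bar_criteria)
    assert res.complies and res.failed_thresholds == ()


def test_unknown_category_raises(bar_criteria):
    food = make_food("F1", category="pasta")
    with pytest.raises(CriteriaError, match="pasta"):
        classify_food(food, bar_criteria)


def test_ineligible_category_never_complies():
    rules = {"sweets": CategoryRule("sweets", eligible=False, thresholds=())}
    criteria = CriteriaSet(name="t", rules=rules)
    res = classify_food(make_food("F1", category="sweets", total_sugar=0), criteria)
    assert res.ineligible_category and not res.complies


# -------------------------------------------------- classify_database

def test_planted_noncompliant_fraction(bar_criteria):
    foods = [
        make_food(f"C{i}", energy=350, added_sugar=5, total_sugar=6, sodium=100,
                  saturated_fat=1, total_fat=4)
        for i in range(6)
    ] + [
        make_food(f"N{i}", energy=350, added_sugar=40, total_sugar=45, sodium=100,
                  saturated_fat=1, total_fat=4)
        for i in range(4)
    ]
    summary = classify_database(FoodDatabase(foods), bar_criteria)
    assert summary.n_processed == 10
    assert summary.n_noncompliant == 4
    assert summary.frac_noncompliant == pytest.approx(0.4)


def test_no_processed_foods_fractions_undefined(bar_criteria):
    db = FoodDatabase([make_food("F1", processed=False, category="bars")])
    summary = classify_database(db, bar_criteria)
    assert summary.n_processed == 0
    assert summary.frac_noncompliant is None


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(1.0, 3.0))
def test_relaxed_criteria_never_shrink_compliant_set(seed, factor):
    rng = np.random.default_rng(seed)
    db, criteria = random_fixture(rng)
    loose = relax_criteria(criteria, factor)
    strict_ok = {fid for fid, r in classify_database(db, criteria).results.items() if r.complies}
    loose_ok = {fid for fid, r in classify_database(db, loose).results.items() if r.complies}
    assert strict_ok <= loose_ok


# -------------------------------------------------------- configs

def test_mcne_style_config_has_19_categories():
    criteria = load_criteria(CONFIG_DIR / "mcne_example.yaml")
    assert criteria.category_count == 19
    assert criteria.ineligible_categories() == set()


def test_cofepris_style_config_has_26_categories_and_exclusions():
    criteria = load_criteria(CONFIG_DIR / "cofepris_example.yaml")
    assert criteria.category_count == 26
    ineligible = criteria.ineligible_categories()
    assert {"soft drinks", "jam and jelly", "honey", "chocolate products"} <= ineligible


def test_unknown_nutrient_token_rejected():
    config = {
        "name": "bad",
        "categories": [
            {"category": "c", "thresholds": [{"nutrient": "vitaminC", "limit": 1}]}
        ],
    }
    with pytest.raises(CriteriaError, match="vitaminC"):
        criteria_from_dict(config)


def test_duplicate_category_rejected():
    config = {"name": "bad", "categories": [{"category": "c"}, {"category": "c"}]}
    with pytest.raises(CriteriaError, match="duplicate"):
        criteria_from_dict(config)


def test_ge_comparator_restricted_to_fiber():
    with pytest.raises(CriteriaError, match="fiber"):
        Threshold("sodium", "ge", 100.0)


# ----------------------------------------------------- estimator API

def test_compliance_classifier_estimator(small_db, bar_criteria):
    clf = ComplianceClassifier(criteria=bar_criteria).fit(small_db)
    assert clf.summary_.n_processed == 3
    pred = clf.predict(small_db)
    assert pred.tolist() == [True, False, False]
    # sklearn param plumbing
    assert clf.get_params()["criteria"] is bar_criteria
    clone = ComplianceClassifier().set_params(criteria=bar_criteria)
    assert clone.get_params()["criteria"] is bar_criteria
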