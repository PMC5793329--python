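import numpy as np
import pandas as pd
import pytest

from fopsim.criteria import CategoryRule, CriteriaSet, Threshold
from fopsim.io import FoodDatabase, FoodItem, NutrientProfile


def make_food(
    food_id,
    category="bars",
    energy=400.0,
    processed=True,
    basis="per_100_g",
    serving_size=None,
    **nutrients,
):
    return FoodItem(
        food_id=food_id,
        name=f"food {food_id}",
        category=category,
        processed=processed,
        basis=basis,
        serving_size=serving_size,
        profile=NutrientProfile(energy=energy, **nutrients),
    )


@pytest.fixture
def bar_criteria():
    """One-category criteria set: cereal-bar-like limits."""
    rule = CategoryRule(
        category="bars",
        eligible=True,
        thresholds=(
            Threshold("added_sugar", "le", 15.0),
            Threshold("sodium", "le", 400.0),
            Threshold("saturated_fat", "le", 10.0, per="pct_of_energy"),
        ),
    )
    return CriteriaSet(name="bar-test", rules={"bars": rule})


@pytest.fixture
def small_db():
    """Three bars: one compliant, one failing sugar+sodium, one failing sugar."""
    return FoodDatabase(
        [
            make_food("B1", energy=350, added_sugar=10, total_sugar=12, sodium=200,
                      saturated_fat=2, total_fat=8),
            make_food("B2", energy=450, added_sugar=30, total_sugar=35, sodium=600,
                      saturated_fat=3, total_fat=10),
            make_food("B3", energy=400, added_sugar=20, total_sugar=25, sodium=100,
                      saturated_fat=1, total_fat=5),
        ]
    )


@pytest.fixture
def simple_design():
    rng = np.random.default_rng(7)
    n = 40
    return pd.DataFrame(
        {
            "person_id": [f"P{i:03d}" for i in range(n)],
            "weight": np.exp(rng.normal(0, 0.4, n)),
            "stratum": rng.integers(0, 4, n),
            "psu": rng.integers(0, 3, n),
        }
    )
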