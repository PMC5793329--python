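"""Weighted quantiles, percent change, and scenario contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fopsim.errors import DataError
from fopsim.survey import (
    compare_scenarios,
    percent_change,
    scenario_summary,
    summarize_by_group,
    weighted_quantile,
)


# ------------------------------------------------------------- oracle

def scan_quantile(values, weights, p):
    """Independent brute-force cumulative-weight scan (same definition:
    first value whose cumulative share strictly exceeds p; average with the
    next order statistic on an exact hit)."""
    pairs = sorted(zip(values, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    for i, (v, w) in enumerate(pairs):
        cum += w
        share = cum / total
        if abs(share - p) <= 1e-12:
            return 0.5 * (v + pairs[i + 1][0]) if i + 1 < len(pairs) else v
        if share > p:
            return v
    return pairs[-1][0]


def test_equal_weight_median_of_three():
    assert weighted_quantile([1, 2, 3], [1, 1, 1], 0.5) == 2


def test_weight_dominance():
    assert weighted_quantile([1, 100], [99, 1], 0.5) == 1


def test_exact_hit_averages_adjacent_order_statistics():
    assert weighted_quantile([1, 2, 3, 4], [1, 1, 1, 1], 0.5) == 2.5


def test_matches_scan_oracle_on_random_samples():
    rng = np.random.default_rng(99)
    for _ in range(200):
        n = int(rng.integers(1, 26))
        values = rng.normal(0, 10, n)
        weights = rng.uniform(0.1, 5.0, n)
        for p in (0.25, 0.5, 0.75):
            got = weighted_quantile(values, weights, p)
            assert got == pytest.approx(scan_quantile(values, weights, p), abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=40),
    st.floats(0.01, 0.99),
)
def test_equal_weights_match_unweighted_reference(values, p):
    got = weighted_quantile(values, np.ones(len(values)), p)
    assert got == pytest.approx(scan_quantile(values, [1.0] * len(values), p))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.05, 10.0))
def test_quantile_monotone_and_scale_equivariant(seed, c):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 30))
    v = rng.normal(0, 5, n)
    w = rng.uniform(0.5, 3, n)
    q25, q50, q75 = (weighted_quantile(v, w, p) for p in (0.25, 0.5, 0.75))
    assert q25 <= q50 <= q75
    for p, q in ((0.25, q25), (0.5, q50), (0.75, q75)):
        assert weighted_quantile(c * v, w, p) == pytest.approx(c * q, rel=1e-12)


def test_quantile_rejects_bad_input():
    with pytest.raises(DataError):
        weighted_quantile([], [], 0.5)
    with pytest.raises(DataError):
        weighted_quantile([1.0], [0.0], 0.5)
    with pytest.raises(DataError):
        weighted_quantile([1.0], [1.0], 1.5)


# ------------------------------------------------------- percent change

@pytest.mark.parametrize(
    "before,after,expected",
    [(1905, 1802, -5.4), (0.25, 0.2, -20.0), (7.3, 7.3, 0.0)],
)
def test_percent_change_values(before, after, expected):
    assert percent_change(before, after) == expected


def test_percent_change_zero_reference_is_missing():
    assert np.isnan(percent_change(0.0, 5.0))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.floats(0.1, 1e4), st.floats(0.0, 1e4), st.floats(0.01, 100.0))
def test_percent_change_invariant_to_rescaling(before, after, c):
    assert percent_change(before, after) == pytest.approx(
        percent_change(c * before, c * after), abs=0.1
    )


# ------------------------------------------------------ scenario contrast

def _intakes(values, name="total_sugar"):
    idx = pd.Index([f"P{i:03d}" for i in range(len(values))], name="person_id")
    return pd.DataFrame({name: values}, index=idx)


def test_identical_scenarios_give_null_contrast(simple_design):
    rng = np.random.default_rng(1)
    x = rng.lognormal(np.log(60), 0.4, len(simple_design))
    res = compare_scenarios(_intakes(x), _intakes(x), simple_design, nutrients=("total_sugar",))
    assert res["total_sugar"].coefficient == pytest.approx(0.0, abs=1e-12)
    assert res["total_sugar"].p_value > 0.99


def test_exact_multiplicative_effect_recovers_log_ratio():
    rng = np.random.default_rng(2)
    n = 500
    design = pd.DataFrame(
        {
            "person_id": [f"P{i:03d}" for i in range(n)],
            "weight": np.exp(rng.normal(0, 0.3, n)),
            "stratum": rng.integers(0, 10, n),
            "psu": rng.integers(0, 5, n),
        }
    )
    x = rng.lognormal(np.log(80), 0.5, n)
    x[0] = 0.2  # keeps the log offset delta = min(x_alt)/2 negligible
    res = compare_scenarios(
        _intakes(x), _intakes(0.6 * x), design, nutrients=("total_sugar",)
    )
    # log(intake + delta) with a small offset: coefficient close to log(0.6)
    assert res["total_sugar"].coefficient == pytest.approx(np.log(0.6), abs=0.02)
    assert res["total_sugar"].p_value < 0.05


def test_cluster_robust_p_matches_textbook_computation():
    """Equal weights, each person its own stratum/PSU: the fitted contrast
    must agree with a hand-rolled OLS + clustered sandwich (Stata small-sample
    correction, t with G-1 df) on a 20-person fixture."""
    rng = np.random.default_rng(3)
    n = 20
    design = pd.DataFrame(
        {
            "person_id": [f"P{i:03d}" for i in range(n)],
            "weight": np.ones(n),
            "stratum": np.arange(n),
            "psu": np.zeros(n, dtype=int),
        }
    )
    x_ref = rng.lognormal(4, 0.5, n)
    x_alt = x_ref * rng.lognormal(-0.2, 0.3, n)
    res = compare_scenarios(_intakes(x_ref), _intakes(x_alt), design, nutrients=("total_sugar",))

    delta = 0.5 * min(np.concatenate([x_ref, x_alt]))
    y = np.log(np.concatenate([x_ref, x_alt]) + delta)
    X = np.column_stack([np.ones(2 * n), np.r_[np.zeros(n), np.ones(n)]])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    xtx_inv = np.linalg.inv(X.T @ X)
    meat = np.zeros((2, 2))
    for g in range(n):  # person g's pair forms one cluster
        Xg, eg = X[[g, g + n]], resid[[g, g + n]]
        s = Xg.T @ eg
        meat += np.outer(s, s)
    G, N, k = n, 2 * n, 2
    correction = (G / (G - 1)) * ((N - 1) / (N - k))
    V = correction * xtx_inv @ meat @ xtx_inv
    t_stat = beta[1] / np.sqrt(V[1, 1])
    p = 2 * stats.t.sf(abs(t_stat), df=G - 1)

    assert res["total_sugar"].coefficient == pytest.approx(beta[1], rel=1e-10)
    assert res["total_sugar"].p_value == pytest.approx(p, rel=1e-6)


def test_all_zero_nutrient_gives_missing_p(simple_design, caplog):
    x = np.zeros(len(simple_design))
    with caplog.at_level("WARNING"):
        res = compare_scenarios(
            _intakes(x), _intakes(x), simple_design, nutrients=("total_sugar",)
        )
    assert np.isnan(res["total_sugar"].p_value)


def test_mismatched_person_sets_raise(simple_design):
    a = _intakes(np.ones(len(simple_design)))
    b = a.iloc[:-1]
    with pytest.raises(DataError):
        compare_scenarios(a, b, simple_design, nutrients=("total_sugar",))


# ------------------------------------------------------- group summaries

def _full_design(n, rng):
    return pd.DataFrame(
        {
            "person_id": [f"P{i:03d}" for i in range(n)],
            "weight": np.exp(rng.normal(0, 0.3, n)),
            "stratum": rng.integers(0, 4, n),
            "psu": rng.integers(0, 3, n),
            "locality": np.where(rng.random(n) < 0.5, "urban", "rural"),
            "sex": np.where(rng.random(n) < 0.5, "female", "male"),
            "age": rng.uniform(20, 59, n),
            "bmi": rng.uniform(18, 35, n),
        }
    )


def test_grouping_none_yields_single_national_row():
    rng = np.random.default_rng(4)
    design = _full_design(30, rng)
    intakes = _intakes(rng.lognormal(4, 0.3, 30))
    out = summarize_by_group(intakes, design, None, nutrients=("total_sugar",))
    assert len(out) == 1
    assert out.loc[0, "level"] == "national"
    assert out.loc[0, "p25"] <= out.loc[0, "median"] <= out.loc[0, "p75"]


def test_group_medians_depend_only_on_members():
    rng = np.random.default_rng(5)
    design = _full_design(60, rng)
    values = rng.lognormal(4, 0.3, 60)
    intakes = _intakes(values)
    out1 = summarize_by_group(intakes, design, "locality", nutrients=("total_sugar",))
    # permute the rural members' values only; urban rows must not move
    rural = design["locality"].to_numpy() == "rural"
    permuted = values.copy()
    permuted[rural] = rng.permutation(values[rural])
    out2 = summarize_by_group(_intakes(permuted), design, "locality", nutrients=("total_sugar",))
    u1 = out1[out1["level"] == "urban"].reset_index(drop=True)
    u2 = out2[out2["level"] == "urban"].reset_index(drop=True)
    pd.testing.assert_frame_equal(u1, u2)


def test_effect_planted_only_in_urban_stratum():
    rng = np.random.default_rng(6)
    n = 400
    design = _full_design(n, rng)
    base = rng.lognormal(np.log(80), 0.4, n)
    after = base.copy()
    urban = design["locality"].to_numpy() == "urban"
    after[urban] *= 0.6
    res = scenario_summary(
        {"scenario1": _intakes(base), "scenario3": _intakes(after)},
        design,
        reference="scenario1",
        grouping="locality",
        nutrients=("total_sugar",),
    )
    s3 = res[res["scenario"] == "scenario3"].set_index("level")
    assert s3.loc["urban", "percent_change"] < s3.loc["rural", "percent_change"]
    assert s3.loc["urban", "percent_change"] == pytest.approx(-40, abs=8)


def test_scenario_summary_reference_change_is_zero(simple_design):
    rng = np.random.default_rng(8)
    intakes = _intakes(rng.lognormal(4, 0.3, len(simple_design)))
    res = scenario_summary(
        {"scenario1": intakes, "scenario2": intakes * 1.1},
        simple_design,
        reference="scenario1",
        nutrients=("total_sugar",),
    )
    ref = res[res["scenario"] == "scenario1"]
    assert (ref["percent_change"] == 0.0).all()
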