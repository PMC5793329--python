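"""Survey-weighted summaries and scenario contrasts.

Quantiles use the cumulative-expansion-weight definition familiar from
survey software: sort the observations, accumulate normalised weights
``F_i``, and return the first value whose cumulative weight strictly exceeds
``p``; when some ``F_i`` equals ``p`` exactly the two adjacent order
statistics are averaged.  With equal weights this reproduces the classic
textbook sample quantile (average the two middle values at an even split).

Scenario contrasts follow the survey-regression recipe: intake is
log-transformed (with a small documented offset for zeros), the two
scenarios' person records are stacked, and a weighted linear model of
log-intake on a scenario indicator is fitted with cluster-robust variance at
the PSU level.  Because each person appears under both scenarios in the same
PSU, the clustering also absorbs the within-person pairing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError
from .io import REPORT_NUTRIENTS

logger = logging.getLogger(__name__)

GROUPING_VARIABLES = ("sex", "age_band", "bmi_class", "region", "locality", "ses")


def weighted_quantile(values, weights, p: float) -> float:
    """Weighted quantile of ``values`` at probability ``p`` (0 < p < 1).

    Returns the smallest value whose normalised cumulative weight reaches
    ``p``; when the cumulative weight hits ``p`` exactly at an order
    statistic, that value is averaged with the next one (linear interpolation
    at the crossing point).  Raises on empty input, non-finite values or
    non-positive weights.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise DataError("weighted_quantile: empty input")
    if v.shape != w.shape:
        raise DataError("weighted_quantile: values and weights differ in length")
    if not np.all(np.isfinite(v)) or not np.all(np.isfinite(w)):
        raise DataError("weighted_quantile: non-finite values or weights")
    if np.any(w <= 0):
        raise DataError("weighted_quantile: weights must be > 0")
    if not 0.0 < p < 1.0:
        raise DataError(f"weighted_quantile: p must be in (0, 1), got {p}")

    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w) / np.sum(w)
    # tolerance for "exactly at p" on the normalised scale
    eps = 1e-12
    idx = int(np.searchsorted(cum, p - eps, side="left"))
    if idx >= v.size:
        return float(v[-1])
    if abs(cum[idx] - p) <= eps and idx + 1 < v.size:
        return float(0.5 * (v[idx] + v[idx + 1]))
    return float(v[idx])


def weighted_median(values, weights) -> float:
    return weighted_quantile(values, weights, 0.5)


def weighted_iqr(values, weights) -> tuple[float, float]:
    """(p25, p75)."""
    return (
        weighted_quantile(values, weights, 0.25),
        weighted_quantile(values, weights, 0.75),
    )


def percent_change(before: float, after: float, decimals: int = 1) -> float:
    """Percent change of ``after`` relative to ``before``, rounded for report.

    Returns ``nan`` (reported as missing) when ``before`` is zero.
    """
    if before == 0:
        logger.warning("percent_change undefined for zero reference value")
        return float("nan")
    return round(100.0 * (after - before) / before, decimals)


@dataclass(frozen=True)
class ContrastResult:
    nutrient: str
    coefficient: float  # scenario-indicator effect on the log scale
    p_value: float
    log_offset: float
    n: int


def _design_frame(design: pd.DataFrame) -> pd.DataFrame:
    for c in ("person_id", "weight"):
        if c not in design.columns:
            raise DataError(f"survey design frame is missing column {c!r}")
    d = design.set_index("person_id")
    if not (d["weight"] > 0).all():
        raise DataError("survey weights must be > 0")
    return d


def _cluster_ids(design: pd.DataFrame) -> pd.Series:
    if "stratum" in design.columns and "psu" in design.columns:
        return design["stratum"].astype(str) + "|" + design["psu"].astype(str)
    return pd.Series(design.index.astype(str), index=design.index)


def compare_scenarios(
    intakes_ref: pd.DataFrame,
    intakes_alt: pd.DataFrame,
    design: pd.DataFrame,
    nutrients: tuple[str, ...] = REPORT_NUTRIENTS,
) -> dict[str, ContrastResult]:
    """Per-nutrient contrast of two scenarios' intakes over the same persons.

    Fits ``log(intake + delta) ~ scenario`` by weighted least squares over
    the stacked person x scenario records, with cluster-robust (PSU)
    standard errors; ``delta`` is half the smallest positive value of the
    nutrient across both scenarios.  A nutrient that is zero for everyone in
    either scenario gets a missing p-value with a warning.
    """
    if not intakes_ref.index.equals(intakes_alt.index):
        common = intakes_ref.index.intersection(intakes_alt.index)
        if len(common) != len(intakes_ref) or len(common) != len(intakes_alt):
            raise DataError("the two intake collections must cover the same persons")
        intakes_alt = intakes_alt.loc[intakes_ref.index]
    d = _design_frame(design).loc[intakes_ref.index]
    w = d["weight"].to_numpy(dtype=float)
    clusters = _cluster_ids(d).to_numpy()

    results: dict[str, ContrastResult] = {}
    for nutrient in nutrients:
        x_ref = intakes_ref[nutrient].to_numpy(dtype=float)
        x_alt = intakes_alt[nutrient].to_numpy(dtype=float)
        if not x_ref.any() or not x_alt.any():
            logger.warning("nutrient %s is all-zero in a scenario; p-value missing", nutrient)
            results[nutrient] = ContrastResult(nutrient, float("nan"), float("nan"), 0.0, len(x_ref))
            continue
        positive = np.concatenate([x_ref[x_ref > 0], x_alt[x_alt > 0]])
        delta = 0.5 * float(positive.min())
        y = np.log(np.concatenate([x_ref, x_alt]) + delta)
        indicator = np.concatenate([np.zeros_like(x_ref), np.ones_like(x_alt)])
        X = sm.add_constant(indicator)
        groups = np.concatenate([clusters, clusters])
        model = sm.WLS(y, X, weights=np.concatenate([w, w]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # t reference with n_clusters - 1 df, as survey software reports
            fit = model.fit(cov_type="cluster", cov_kwds={"groups": groups}, use_t=True)
        coef = float(fit.params[1])
        p = float(fit.pvalues[1])
        se = float(fit.bse[1])
        if np.isnan(p) or se < 1e-12:
            # degenerate fit: identical scenarios make the paired cluster
            # variance exactly zero, leaving p to rounding noise
            p = 1.0 if abs(coef) < 1e-9 else 0.0
        results[nutrient] = ContrastResult(
            nutrient=nutrient,
            coefficient=coef,
            p_value=p,
            log_offset=delta,
            n=len(x_ref),
        )
    return results


def add_group_columns(participants: pd.DataFrame) -> pd.DataFrame:
    """Derive the banded grouping columns used in subgroup summaries."""
    p = participants.copy()
    if "age" in p.columns:
        p["age_band"] = np.where(p["age"] < 40, "20-39", "40-59")
    if "bmi" in p.columns:
        p["bmi_class"] = pd.cut(
            p["bmi"],
            bins=[-np.inf, 18.5, 25, 30, np.inf],
            labels=["underweight", "normal", "overweight", "obesity"],
        ).astype(str)
    return p


def summarize_by_group(
    intakes: pd.DataFrame,
    design: pd.DataFrame,
    grouping: str | None = None,
    nutrients: tuple[str, ...] = REPORT_NUTRIENTS,
) -> pd.DataFrame:
    """Weighted median and IQR per nutrient, overall or within group levels.

    ``grouping=None`` (or ``"none"``) yields one national row per nutrient.
    Each level's quantiles use only its own members; empty levels are
    omitted with a warning.
    """
    if grouping in (None, "none"):
        groups = {"national": intakes.index}
    else:
        d = add_group_columns(_design_frame(design).loc[intakes.index])
        if grouping not in d.columns:
            raise DataError(f"unknown grouping variable {grouping!r}")
        groups = {
            str(level): idx.index
            for level, idx in d.groupby(grouping, observed=True)
            if len(idx)
        }
    d_all = _design_frame(design)
    rows = []
    for level, idx in groups.items():
        if len(idx) == 0:
            logger.warning("group level %s is empty; omitted", level)
            continue
        w = d_all.loc[idx, "weight"].to_numpy(dtype=float)
        for nutrient in nutrients:
            v = intakes.loc[idx, nutrient].to_numpy(dtype=float)
            p25, p75 = weighted_iqr(v, w)
            rows.append(
                {
                    "group": grouping or "none",
                    "level": level,
                    "nutrient": nutrient,
                    "median": weighted_median(v, w),
                    "p25": p25,
                    "p75": p75,
                    "n": len(idx),
                }
            )
    return pd.DataFrame(rows)


def scenario_summary(
    intakes_by_scenario: dict[str, pd.DataFrame],
    design: pd.DataFrame,
    reference: str,
    grouping: str | None = None,
    nutrients: tuple[str, ...] = REPORT_NUTRIENTS,
) -> pd.DataFrame:
    """Build the per-scenario summary table (median, IQR, percent change vs
    the reference scenario, contrast p-value)."""
    if reference not in intakes_by_scenario:
        raise DataError(f"reference scenario {reference!r} not among results")
    pieces = []
    ref = intakes_by_scenario[reference]
    for label, intakes in intakes_by_scenario.items():
        summ = summarize_by_group(intakes, design, grouping, nutrients)
        summ.insert(0, "scenario", label)
        if label == reference:
            summ["percent_change"] = 0.0
            summ["p_value"] = np.nan
        else:
            contrasts = compare_scenarios(ref, intakes, design, nutrients)
            ref_summ = summarize_by_group(ref, design, grouping, nutrients)
            ref_medians = ref_summ.set_index(["level", "nutrient"])["median"]
            summ["percent_change"] = [
                percent_change(ref_medians.loc[(row.level, row.nutrient)], row.median)
                for row in summ.itertuples()
            ]
            summ["p_value"] = [contrasts[n].p_value for n in summ["nutrient"]]
        pieces.append(summ)
    return pd.concat(pieces, ignore_index=True)


__all__ = [
    "GROUPING_VARIABLES",
    "weighted_quantile",
    "weighted_median",
    "weighted_iqr",
    "percent_change",
    "ContrastResult",
    "compare_scenarios",
    "add_group_columns",
    "summarize_by_group",
    "scenario_summary",
]
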