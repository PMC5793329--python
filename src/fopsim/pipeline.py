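"""End-to-end pipeline: load -> exclude -> classify -> replace -> summarise.

A run is described by a :class:`RunConfig` (usually parsed from YAML):
paths to the three input tables, one or more criteria configs, the scenario
list with exempt/restricted category sets, grouping variables, and an output
directory.  ``run_pipeline`` writes, per criteria set, the replacement map,
the scenario summary table (median, p25, p75, percent change, p-value) and a
percent-change file with a companion plot, plus the exclusion audit and a
run log; a consistency check re-derives every percent change from the
medians table before anything is written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .criteria import CriteriaSet, classify_database, load_criteria
from .errors import DataError, PipelineError
from .preprocess import aggregate_intake, apply_exclusions
from .replacement import ScenarioReplacer
from .survey import REPORT_NUTRIENTS, compare_scenarios, percent_change, scenario_summary

logger = logging.getLogger(__name__)

DEFAULT_EXEMPT = ("soft drinks", "bakery products", "dairy drinks")


@dataclass
class RunConfig:
    food_db: str
    recalls: str
    participants: str
    criteria: list[str]
    output_dir: str
    scenarios: tuple[int, ...] = (1, 2, 3)
    exempt_categories: tuple[str, ...] = DEFAULT_EXEMPT
    restrict_to_categories: tuple[str, ...] | None = None
    grouping: tuple[str, ...] = ("none",)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.criteria:
            raise PipelineError("run config needs at least one criteria file")
        if not self.scenarios:
            raise PipelineError("run config needs at least one scenario")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent

        def resolve(p: str) -> str:
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        return cls(
            food_db=resolve(raw["food_db"]),
            recalls=resolve(raw["recalls"]),
            participants=resolve(raw["participants"]),
            criteria=[resolve(p) for p in raw["criteria"]],
            output_dir=resolve(raw["output_dir"]),
            scenarios=tuple(raw.get("scenarios", (1, 2, 3))),
            exempt_categories=tuple(raw.get("exempt_categories", DEFAULT_EXEMPT)),
            restrict_to_categories=(
                tuple(raw["restrict_to_categories"])
                if raw.get("restrict_to_categories")
                else None
            ),
            grouping=tuple(raw.get("grouping", ("none",))),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "-" for ch in name.lower()).strip("-")


def compare_criteria(
    intakes_a: pd.DataFrame,
    intakes_b: pd.DataFrame,
    design: pd.DataFrame,
    label_a: str = "A",
    label_b: str = "B",
) -> pd.DataFrame:
    """Per-nutrient contrast of two criteria sets' scenario-3 intakes.

    Rows: nutrient, the two weighted medians, difference (B - A), and the
    p-value of the weighted log-linear contrast.  Swapping the arguments
    flips the sign of every difference.
    """
    if set(intakes_a.index) != set(intakes_b.index):
        raise DataError("criteria comparison requires identical retained persons")
    intakes_b = intakes_b.loc[intakes_a.index]
    contrasts = compare_scenarios(intakes_a, intakes_b, design)
    d = design.set_index("person_id").loc[intakes_a.index]
    from .survey import weighted_median

    w = d["weight"].to_numpy(dtype=float)
    rows = []
    for nutrient in REPORT_NUTRIENTS:
        med_a = weighted_median(intakes_a[nutrient].to_numpy(dtype=float), w)
        med_b = weighted_median(intakes_b[nutrient].to_numpy(dtype=float), w)
        rows.append(
            {
                "nutrient": nutrient,
                f"median_{label_a}": med_a,
                f"median_{label_b}": med_b,
                "difference": med_b - med_a,
                "p_value": contrasts[nutrient].p_value,
            }
        )
    return pd.DataFrame(rows)


def check_consistency(table: pd.DataFrame, pct_file: pd.DataFrame) -> None:
    """Assert every percent change in the figure file is recomputable from
    the medians table (to printed precision)."""
    medians = table.set_index(["scenario", "level", "nutrient"])["median"]
    for row in pct_file.itertuples():
        before = medians.loc[("scenario1", row.level, row.nutrient)]
        after = medians.loc[(row.scenario, row.level, row.nutrient)]
        expected = percent_change(before, after)
        if not (np.isnan(expected) and np.isnan(row.percent_change)):
            if abs(expected - row.percent_change) > 0.05 + 1e-9:
                raise PipelineError(
                    f"inconsistent percent change for {row.nutrient} "
                    f"({row.scenario}): table implies {expected}, file has "
                    f"{row.percent_change}"
                )


def _plot_percent_changes(pct: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    national = pct[pct["level"] == "national"]
    scenarios = sorted(national["scenario"].unique())
    nutrients = list(REPORT_NUTRIENTS)
    fig, ax = plt.subplots(figsize=(8, 4.5))
    width = 0.8 / max(len(scenarios), 1)
    x = np.arange(len(nutrients))
    for i, sc in enumerate(scenarios):
        sub = national[national["scenario"] == sc].set_index("nutrient")
        vals = [sub.loc[n, "percent_change"] if n in sub.index else np.nan for n in nutrients]
        ax.bar(x + i * width, vals, width, label=sc)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xticks(x + width * (len(scenarios) - 1) / 2)
    ax.set_xticklabels(nutrients, rotation=30, ha="right")
    ax.set_ylabel("median change (%)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_criteria_analysis(
    db: fio.FoodDatabase,
    criteria: CriteriaSet,
    recalls: pd.DataFrame,
    participants: pd.DataFrame,
    scenarios: tuple[int, ...] = (1, 2, 3),
    exempt_categories: tuple[str, ...] = DEFAULT_EXEMPT,
    restrict_to_categories: tuple[str, ...] | None = None,
    grouping: str | None = None,
) -> dict:
    """Run all scenarios for one criteria set over already-retained persons.

    Returns a dict with the replacement map, per-scenario intake frames, the
    summary table and the percent-change frame.
    """
    exempt = tuple(c for c in exempt_categories if c in db.categories())
    intakes_by_scenario: dict[str, pd.DataFrame] = {}
    replacer = None
    retained = set(participants["person_id"])
    recalls_r = recalls[recalls["person_id"].isin(retained)]
    for sc in scenarios:
        replacer = ScenarioReplacer(
            criteria=criteria,
            scenario=sc,
            exempt_categories=exempt,
            restrict_to_categories=restrict_to_categories,
        ).fit(db)
        modified = replacer.transform(recalls_r)
        intakes = aggregate_intake(modified, db)
        intakes = intakes.reindex(sorted(retained)).fillna(0.0)
        intakes_by_scenario[f"scenario{sc}"] = intakes

    table = scenario_summary(
        intakes_by_scenario, participants, reference="scenario1", grouping=grouping
    )
    pct = table[table["scenario"] != "scenario1"][
        ["scenario", "level", "nutrient", "percent_change", "p_value"]
    ].copy()
    pct["significant"] = pct["p_value"] < 0.05
    check_consistency(table, pct)
    return {
        "criteria": criteria,
        "replacement_map": replacer.replacement_map_ if replacer else None,
        "intakes": intakes_by_scenario,
        "table": table,
        "percent_changes": pct,
        "classification": classify_database(db, criteria),
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow and write all outputs; returns the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("fopsim")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        return _run_pipeline(config, out)
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_pipeline(config: RunConfig, out: Path) -> Path:
    logger.info("stage load: reading inputs")
    db = fio.load_food_db(config.food_db)
    recalls = fio.load_recalls(config.recalls, db)
    participants = fio.load_participants(config.participants)

    logger.info("stage preprocess: aggregating %d recall entries", len(recalls))
    intakes_raw = aggregate_intake(recalls, db)
    intakes_all = intakes_raw.reindex(participants["person_id"]).fillna(0.0)
    retained, audit = apply_exclusions(participants, intakes_all)
    with open(out / "audit.json", "w", encoding="utf-8") as fh:
        json.dump(audit.to_dict(), fh, indent=2)
    logger.info("stage preprocess: retained %d of %d", audit.final_n, audit.initial_n)

    scenario3_intakes: dict[str, pd.DataFrame] = {}
    for crit_path in config.criteria:
        criteria = load_criteria(crit_path)
        slug = _slug(criteria.name)
        logger.info("stage criteria %s: %d categories", criteria.name, criteria.category_count)
        result = run_criteria_analysis(
            db,
            criteria,
            recalls,
            retained,
            scenarios=config.scenarios,
            exempt_categories=config.exempt_categories,
            restrict_to_categories=config.restrict_to_categories,
        )
        result["replacement_map"].to_frame().to_csv(
            out / f"replacement_map_{slug}.csv", index=False
        )
        fio.write_scenario_table(result["table"], out / f"table_{slug}.csv")
        result["percent_changes"].to_csv(out / f"percent_change_{slug}.csv", index=False)
        _plot_percent_changes(
            result["percent_changes"], out / f"percent_change_{slug}.png", criteria.name
        )
        summ = result["classification"]
        with open(out / f"classification_{slug}.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "criteria": criteria.name,
                    "n_processed": summ.n_processed,
                    "n_compliant": summ.n_compliant,
                    "n_noncompliant": summ.n_noncompliant,
                    "n_replaceable": summ.n_replaceable,
                    "frac_noncompliant": summ.frac_noncompliant,
                    "frac_replaceable": summ.frac_replaceable,
                },
                fh,
                indent=2,
            )
        if "scenario3" in result["intakes"]:
            scenario3_intakes[criteria.name] = result["intakes"]["scenario3"]

    names = list(scenario3_intakes)
    if len(names) >= 2:
        a, b = names[0], names[1]
        comp = compare_criteria(
            scenario3_intakes[a], scenario3_intakes[b], retained, label_a=a, label_b=b
        )
        comp.to_csv(out / f"comparison_{_slug(a)}_vs_{_slug(b)}.csv", index=False)
    logger.info("pipeline complete: outputs in %s", out)
    return out


__all__ = [
    "DEFAULT_EXEMPT",
    "RunConfig",
    "compare_criteria",
    "check_consistency",
    "run_criteria_analysis",
    "run_pipeline",
]
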