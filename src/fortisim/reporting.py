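"""Comparison tables and the end-to-end pipeline.

Two fortification methods are compared on a standard basket of the eight
vehicles (100 g of each, 800 g total):

* method 1 (computational): a uniform level in ug per 100 g of food, so each
  100-g portion of any vehicle carries the same amount;
* method 2 (formula-based): a safe addition in ug per 100 kcal, so each
  food's contribution scales with its energy density.

``country_comparison`` reproduces the published per-100-kcal vitamin D
figures for six European countries and Iran and their mean.

``run_pipeline`` wires the full analysis: generate (or load) a population,
simulate intakes, search fortification plans, evaluate the safe-addition
formulas, and emit the comparison tables into a report directory. Report
data files are deterministic for a fixed config and seed; the run timestamp
lives only in ``run_metadata.json`` and the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import formulas as _formulas
from .errors import EmptyInputError, ParameterError, PipelineError
from .intake import (
    DEFAULT_VEHICLES,
    THRESHOLD_PRESETS,
    FoodVehicle,
    FortificationPlan,
    SupplementScenario,
    Thresholds,
    export_intakes,
    validate_vehicles,
)
from .optimize import GridSpec, OptimizationResult, optimize_plan
from .population import (
    DEFAULT_VEHICLE_CONSUMPTION,
    PopulationParams,
    generate_population,
    population_to_frame,
    read_population,
    summarize_population,
)

logger = logging.getLogger("fortisim")

__all__ = [
    "DEFAULT_CONFIG",
    "TABLE_COUNTRY_UG_PER_100KCAL",
    "PRINTED_KCAL_MULTIPLIERS",
    "Basket",
    "MethodComparison",
    "ReportBundle",
    "compare_fortification_methods",
    "country_comparison",
    "default_basket",
    "load_config",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Method comparison (uniform ug/100 g vs ug/100 kcal)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Basket:
    """A consumption basket: (vehicle, grams) items."""

    items: tuple[tuple[FoodVehicle, float], ...]

    def validate(self) -> None:
        if not self.items:
            raise EmptyInputError("basket must contain at least one item")
        for vehicle, grams in self.items:
            vehicle.validate()
            if grams <= 0:
                raise ParameterError(f"basket grams for {vehicle.name!r} must be > 0")

    @property
    def total_grams(self) -> float:
        return float(sum(g for _, g in self.items))


def default_basket(grams_each: float = 100.0) -> Basket:
    """100 g of each of the eight vehicles (800 g total) unless overridden."""
    return Basket(tuple((v, grams_each) for v in DEFAULT_VEHICLES))


#: Two-decimal kcal-portion multipliers (100-kcal portions per 100 g) as
#: printed in the published comparison; the full-precision alternative is
#: kcal_per_100g / 100 (0.375 vs 0.37 for bread, 1.666 vs 1.67 for cheese).
PRINTED_KCAL_MULTIPLIERS: Mapping[str, float] = {
    "whole_bread": 0.37,
    "white_bread": 0.37,
    "whole_milk": 0.62,
    "low_fat_milk": 0.5,
    "yogurt": 0.66,
    "doogh": 0.5,
    "cheese": 1.67,
    "butter": 9.0,
}


@dataclass(frozen=True)
class MethodComparison:
    per_food: tuple[tuple[str, float, float], ...]  # (vehicle, method1_ug, method2_ug)
    total_method1: float
    total_method2: float
    total_kcal: float

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.per_food, columns=["vehicle", "method1_ug", "method2_ug"])
        return frame


def compare_fortification_methods(
    basket: Basket,
    level_ug_per_100g: float,
    fa_ug_per_100kcal: float,
    use_printed_multipliers: bool = True,
) -> MethodComparison:
    """Vitamin D delivered by each method, per food and in total.

    method 1: grams/100 x level (ug per 100 g of food);
    method 2: fa x 100-kcal portions, where the portion count per food is
    either the printed two-decimal multiplier (default, reproducing the
    published totals exactly) or the full-precision
    kcal_per_100g x grams / 100 / 100.
    """
    basket.validate()
    if level_ug_per_100g < 0 or fa_ug_per_100kcal < 0:
        raise ParameterError("level and fa must be >= 0")
    per_food = []
    total_kcal = 0.0
    for vehicle, grams in basket.items:
        m1 = grams / 100.0 * level_ug_per_100g
        if use_printed_multipliers and vehicle.name in PRINTED_KCAL_MULTIPLIERS:
            portions = PRINTED_KCAL_MULTIPLIERS[vehicle.name] * grams / 100.0
        else:
            portions = vehicle.kcal_per_100g * grams / 100.0 / 100.0
        m2 = fa_ug_per_100kcal * portions
        per_food.append((vehicle.name, m1, m2))
        total_kcal += vehicle.kcal_per_100g * grams / 100.0
    return MethodComparison(
        per_food=tuple(per_food),
        total_method1=float(sum(m1 for _, m1, _ in per_food)),
        total_method2=float(sum(m2 for _, _, m2 in per_food)),
        total_kcal=total_kcal,
    )


# ---------------------------------------------------------------------------
# Country comparison
# ---------------------------------------------------------------------------

#: Vitamin D from all sources, ug per 100 kcal, by country (ILSI model).
TABLE_COUNTRY_UG_PER_100KCAL: Mapping[str, float] = {
    "Denmark": 1.8,
    "France": 1.3,
    "Ireland": 1.7,
    "Germany": 3.4,
    "Holland": 1.8,
    "UK": 2.0,
    "Iran": 2.1,
}


def country_comparison(
    values: Mapping[str, float] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Mean ug/100 kcal across countries (1 d.p.) and the country table."""
    if values is None:
        values = TABLE_COUNTRY_UG_PER_100KCAL
    if not values:
        raise EmptyInputError("country_comparison requires at least one country")
    frame = pd.DataFrame(
        {"country": list(values), "vitd_ug_per_100kcal": list(values.values())}
    )
    mean = _formulas.round_half_up(frame["vitd_ug_per_100kcal"].mean(), 1)
    return mean, frame


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "population": {
        "n_individuals": 2000,
        "mean_baseline_vitd": 4.0,
        "sd_log_baseline": 0.6,
        "mean_energy": 2000.0,
        "p95_energy": 4200.0,
        "supplement_iu": 0.0,
        "appetite_sd_log": 0.0,
        "vehicle_consumption": {
            v: list(mc) for v, mc in DEFAULT_VEHICLE_CONSUMPTION.items()
        },
    },
    "population_csv": None,  # overrides "population" when set
    "preset": "iom",
    "grid": {"levels_allowed": [1.0, 2.0, 3.0, 4.0], "uniform_only": True},
    "supplement_scenario_iu": 1000.0,  # safety-constraint scenario; 0 disables
    "formulas": {
        "ul": 5.0,
        "ci95": 0.05,
        "ei95": 18.8,
        "pff": 0.11,
        "portions": 42.0,
        "fortified_fraction": 0.5,
        "rda_ug": 20.0,
    },
    "pff_list": [1.0, 0.5, 0.25, 0.11, 0.05],
    "seed": 42,
}


def load_config(path) -> dict:
    """Load a YAML or JSON config, overlaying the shipped defaults."""
    text = Path(path).read_text(encoding="utf-8")
    loaded = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(loaded, dict):
        raise ParameterError("config must be a mapping")
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in loaded.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


@dataclass
class ReportBundle:
    summary: "object"
    optimization: OptimizationResult
    safe_addition: pd.DataFrame
    method_comparison: MethodComparison
    country_mean: float
    out_dir: Path


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(config: Mapping | str | Path, out_dir, seed: int | None = None) -> ReportBundle:
    """Run generate -> intake -> optimize -> formulas -> comparisons.

    ``config`` is a mapping or a YAML/JSON path; ``seed`` overrides the
    config seed. Writes CSV/JSON outputs plus ``pipeline.log`` into
    ``out_dir`` (created if needed).
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        merged = json.loads(json.dumps(DEFAULT_CONFIG))
        for key, value in dict(config).items():
            if isinstance(value, dict) and isinstance(merged.get(key), dict):
                merged[key].update(value)
            else:
                merged[key] = value
        config = merged
    if seed is not None:
        config["seed"] = int(seed)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    try:
        # --- generate/load ---------------------------------------------
        if config.get("population_csv"):
            population = _stage("load_population")(read_population, config["population_csv"])
        else:
            pop_cfg = dict(config["population"])
            pop_cfg["vehicle_consumption"] = {
                v: tuple(mc) for v, mc in pop_cfg["vehicle_consumption"].items()
            }
            params = PopulationParams(seed=int(config["seed"]), **pop_cfg)
            population = _stage("generate")(generate_population, params)
        logger.info("population: %d records", len(population))
        population_to_frame(population).to_csv(out / "population.csv", index=False, encoding="utf-8")
        summary = _stage("summarize")(summarize_population, population)
        (out / "population_summary.json").write_text(
            json.dumps(dataclasses.asdict(summary), indent=2, sort_keys=True), encoding="utf-8"
        )

        # --- optimize --------------------------------------------------
        thresholds = THRESHOLD_PRESETS[config["preset"]]
        grid = GridSpec(
            levels_allowed=tuple(float(x) for x in config["grid"]["levels_allowed"]),
            uniform_only=bool(config["grid"]["uniform_only"]),
        )
        dose = float(config.get("supplement_scenario_iu") or 0.0)
        scenario = SupplementScenario.dose(dose) if dose > 0 else SupplementScenario.none()
        vehicles = DEFAULT_VEHICLES
        validate_vehicles(vehicles)
        result = _stage("optimize")(
            optimize_plan, population, grid, thresholds, scenario, vehicles
        )
        if not result.feasible:
            logger.warning("no feasible plan; reporting least-violating plan")
        (out / "optimization.json").write_text(
            json.dumps(result.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
        )
        _stage("intake")(
            export_intakes, population, result.best_plan, scenario, out / "intakes.csv"
        )

        # --- formulas --------------------------------------------------
        base = _formulas.FormulaInputs(**config["formulas"])
        scenarios = [("flynn", 0.0)]
        if dose > 0:
            base_si = base.with_supplement_iu(dose).si
            scenarios.append(("rasmussen", base_si))
        else:
            scenarios.append(("rasmussen", 0.0))
        table = _stage("formulas")(
            _formulas.safe_addition_table, list(config["pff_list"]), scenarios, base
        )
        table.to_csv(out / "safe_addition.csv", index=False, encoding="utf-8")

        # --- comparisons -----------------------------------------------
        fa = _formulas.flynn_fa(base)
        # headline convention: FA in RDA units read as ug per 100 kcal, 1 d.p.
        fa_ug = _formulas.round_half_up(fa, 1)
        best_uniform = (
            min(result.best_plan.levels.values()) if result.best_plan.levels else 0.0
        )
        comparison = _stage("compare")(
            compare_fortification_methods, default_basket(), best_uniform, fa_ug
        )
        comparison.to_frame().to_csv(out / "method_comparison.csv", index=False, encoding="utf-8")
        country_mean, country_frame = _stage("country")(country_comparison)
        country_frame.to_csv(out / "country_comparison.csv", index=False, encoding="utf-8")

        (out / "run_metadata.json").write_text(
            json.dumps(
                {
                    "timestamp": datetime.now(timezone.utc).isoformat(),
                    "seed": int(config["seed"]),
                    "preset": config["preset"],
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        logger.info(
            "done: best plan %s, flynn FA %.4f RDA/100 kcal",
            dict(result.best_plan.levels),
            fa,
        )
        return ReportBundle(
            summary=summary,
            optimization=result,
            safe_addition=table,
            method_comparison=comparison,
            country_mean=country_mean,
            out_dir=out,
        )
    finally:
        logger.removeHandler(handler)
        handler.close()
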