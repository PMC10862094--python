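"""Exhaustive fortification-plan search under a hard UL constraint.

A plan assigns each fortifiable vehicle a level from a small discrete grid
(default 1-4 ug per 100 g). Two readings of "optimal" are combined:

* feasibility (hard constraint): no individual's total intake may exceed the
  UL — a single person above the UL invalidates a plan;
* objective: among feasible plans, minimize the fraction of the population
  outside the acceptable band [RI, UL].

Ties are broken by the smallest total added ug across the plan's levels
(the cheapest equally-performing plan), then by enumeration order.

Supplement handling: the safety constraint is evaluated under the supplement
scenario passed in (worst case: every individual takes the scenario dose),
while the coverage objective is evaluated on diet-only intake by default —
adequacy is judged for people who do not take supplements, safety for those
who do. Pass ``coverage_scenario`` explicitly to change this.

With 8 vehicles and 4 levels the full per-vehicle grid has 4^8 = 65,536
plans; enumeration is exact and no heuristic search is needed. The uniform
grid (one shared level, matching the reported analysis) has 4 plans.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, EmptyInputError, ParameterError
from .intake import (
    CoverageMetrics,
    FoodVehicle,
    FortificationPlan,
    SupplementScenario,
    Thresholds,
    coverage_metrics,
    fortifiable_names,
    grams_matrix,
)
from .population import DietaryRecord

__all__ = [
    "GridSpec",
    "OptimizationResult",
    "enumerate_plans",
    "is_feasible",
    "optimize_plan",
]


@dataclass(frozen=True)
class GridSpec:
    """Discrete levels to search, in ug per 100 g."""

    levels_allowed: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    uniform_only: bool = True

    def validate(self) -> None:
        if not self.levels_allowed:
            raise ParameterError("levels_allowed must be non-empty")
        if any(l < 0 for l in self.levels_allowed):
            raise ParameterError("levels_allowed must all be >= 0")
        if any(b <= a for a, b in zip(self.levels_allowed, self.levels_allowed[1:])):
            raise ParameterError("levels_allowed must be strictly increasing")


def enumerate_plans(
    grid: GridSpec, vehicles: Sequence[FoodVehicle]
) -> list[FortificationPlan]:
    """All candidate plans in deterministic lexicographic order.

    Vehicles are ordered by name; per-vehicle grids enumerate level tuples
    lexicographically, so the all-lowest plan comes first. Uniform grids
    yield one plan per allowed level, ascending.
    """
    grid.validate()
    names = fortifiable_names(vehicles)
    if not names:
        raise ConfigurationError("no fortifiable vehicles to enumerate plans over")
    if grid.uniform_only:
        return [FortificationPlan.uniform(level, names) for level in grid.levels_allowed]
    return [
        FortificationPlan(dict(zip(names, combo)))
        for combo in itertools.product(grid.levels_allowed, repeat=len(names))
    ]


def _intake_vectors(
    population: Sequence[DietaryRecord],
    names: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    if not population:
        raise EmptyInputError("optimizer requires a non-empty population")
    baseline = np.array([r.baseline_vitd for r in population])
    return baseline, grams_matrix(population, names)


def is_feasible(
    plan: FortificationPlan,
    population: Sequence[DietaryRecord],
    thresholds: Thresholds,
    scenario: SupplementScenario = SupplementScenario.none(),
) -> bool:
    """True iff no individual's total intake exceeds the UL under the plan."""
    thresholds.validate()
    scenario.validate()
    plan.validate()
    names = sorted(plan.levels)
    baseline, grams = _intake_vectors(population, names)
    levels = np.array([plan.levels[v] for v in names])
    totals = baseline + grams @ levels / 100.0 + scenario.supplement_ug
    return bool(totals.max() <= thresholds.ul)


@dataclass
class OptimizationResult:
    """Outcome of the exhaustive search.

    When ``feasible`` is False no plan satisfied the UL constraint;
    ``best_plan`` then carries the least-violating plan (smallest maximum
    intake) for diagnostics and ``ranking`` is empty.
    """

    best_plan: FortificationPlan
    best_metrics: CoverageMetrics
    feasible: bool
    feasible_count: int
    evaluated_count: int
    ranking: list[tuple[FortificationPlan, CoverageMetrics]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "feasible": self.feasible,
            "feasible_count": self.feasible_count,
            "evaluated_count": self.evaluated_count,
            "best_plan": dict(self.best_plan.levels),
            "best_metrics": self.best_metrics.to_dict(),
            "ranking": [
                {"plan": dict(p.levels), "metrics": m.to_dict()}
                for p, m in self.ranking
            ],
        }


def optimize_plan(
    population: Sequence[DietaryRecord],
    grid: GridSpec,
    thresholds: Thresholds,
    scenario: SupplementScenario = SupplementScenario.none(),
    vehicles: Sequence[FoodVehicle] | None = None,
    coverage_scenario: SupplementScenario | None = None,
) -> OptimizationResult:
    """Evaluate every plan on the grid and return the constrained optimum.

    Parameters
    ----------
    scenario:
        Supplement scenario for the UL feasibility check (safety is judged
        assuming everyone takes the scenario dose).
    vehicles:
        Vehicle set to fortify. Defaults to one vehicle per food name
        appearing in the population's grams, all fortifiable.
    coverage_scenario:
        Scenario for the coverage objective; defaults to no supplement use
        (diet-only adequacy).
    """
    grid.validate()
    thresholds.validate()
    scenario.validate()
    if coverage_scenario is None:
        coverage_scenario = SupplementScenario.none()
    coverage_scenario.validate()
    if vehicles is None:
        names_all = sorted({v for r in population for v in r.grams})
        vehicles = tuple(FoodVehicle(n, kcal_per_100g=100.0) for n in names_all)

    plans = enumerate_plans(grid, vehicles)
    names = fortifiable_names(vehicles)
    baseline, grams = _intake_vectors(population, names)
    supp_feas = scenario.supplement_ug
    supp_cov = coverage_scenario.supplement_ug

    scored: list[tuple[float, float, int, FortificationPlan, CoverageMetrics]] = []
    least_violation = None  # (max_excess, index, plan, metrics)
    for idx, plan in enumerate(plans):
        levels = np.array([plan.levels[v] for v in names])
        added = grams @ levels / 100.0
        max_total = float((baseline + added).max()) + supp_feas
        if max_total > thresholds.ul:
            if least_violation is None or max_total < least_violation[0]:
                cov = coverage_metrics(baseline + added + supp_cov, thresholds)
                least_violation = (max_total, idx, plan, cov)
            continue
        metrics = coverage_metrics(baseline + added + supp_cov, thresholds)
        objective = metrics.frac_below_ri + metrics.frac_above_ul
        scored.append((objective, plan.total_level, idx, plan, metrics))

    if not scored:
        assert least_violation is not None
        _, _, plan, metrics = least_violation
        return OptimizationResult(
            best_plan=plan,
            best_metrics=metrics,
            feasible=False,
            feasible_count=0,
            evaluated_count=len(plans),
        )

    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    best = scored[0]
    return OptimizationResult(
        best_plan=best[3],
        best_metrics=best[4],
        feasible=True,
        feasible_count=len(scored),
        evaluated_count=len(plans),
        ranking=[(p, m) for _, _, _, p, m in scored],
    )
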