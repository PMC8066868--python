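"""Risk-group cutoff scenario analysis and the ending-age variant.

The base case stratifies at the 60th/95th PRS percentiles, for which the
observed Asian-population proportions are 0.51/0.41/0.08. For the
alternative cutoffs no observed proportions are published, so the nominal
percentile widths are used as population proportions (a logged, configurable
choice); multipliers stay fixed at 0.5x/1x/2x.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .cea import CEResult, icer
from .engine import ArmOutcomes, run_strategy
from .parameters import ParameterSet, RiskGroup, RiskStratification, ValidationError
from .strategies import build_current_strategy, build_tailored_strategy, truncate_strategy

__all__ = [
    "CutoffScenario",
    "ScenarioResult",
    "printed_scenarios",
    "run_scenario",
    "run_all_scenarios",
    "run_ending_age_variant",
    "table2_frame",
]

log = logging.getLogger("prscreen")

MULTIPLIERS = {"low": 0.5, "intermediate": 1.0, "high": 2.0}


@dataclass(frozen=True)
class CutoffScenario:
    name: str
    widths: tuple[float, float, float]  # percentile widths low/intermediate/high
    proportions: tuple[float, float, float]  # population proportions used

    def validate(self) -> None:
        if abs(sum(self.widths) - 100.0) > 1e-9:
            raise ValidationError(f"{self.name}: percentile widths must sum to 100")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValidationError(f"{self.name}: proportions must sum to 1")

    def stratification(self) -> RiskStratification:
        names = ("low", "intermediate", "high")
        groups, pct = [], 0.0
        for name, width, prop in zip(names, self.widths, self.proportions):
            groups.append(
                RiskGroup(
                    name=name,
                    percentile_low=pct,
                    percentile_high=pct + width,
                    population_proportion=prop,
                    risk_multiplier=MULTIPLIERS[name],
                )
            )
            pct += width
        return RiskStratification(tuple(groups))


def printed_scenarios(params: ParameterSet) -> list[CutoffScenario]:
    """Base case plus the three alternative percentile-cutoff scenarios."""
    base_props = tuple(g.population_proportion for g in params.strat.groups)
    scenarios = [CutoffScenario("60L-35I-5H", (60, 35, 5), base_props)]
    for name, widths in (
        ("60L-30I-10H", (60, 30, 10)),
        ("40L-55I-5H", (40, 55, 5)),
        ("40L-50I-10H", (40, 50, 10)),
    ):
        props = tuple(w / 100.0 for w in widths)
        scenarios.append(CutoffScenario(name, widths, props))
    return scenarios


def scenario_by_name(name: str, params: ParameterSet) -> CutoffScenario:
    for sc in printed_scenarios(params):
        if sc.name == name:
            return sc
    raise ValidationError(f"unknown scenario {name!r}")


@dataclass(frozen=True)
class ScenarioResult:
    scenario: CutoffScenario
    current: ArmOutcomes
    tailored: ArmOutcomes
    ce: CEResult


def run_scenario(scenario: CutoffScenario, params: ParameterSet) -> ScenarioResult:
    """Deterministic model with the tailored arm rebuilt for the scenario."""
    scenario.validate()
    strat = scenario.stratification()
    strat.validate()
    scenario_params = replace(params, strat=strat)
    current = run_strategy(build_current_strategy(params.config), params)
    tailored = run_strategy(
        build_tailored_strategy(strat, params.config), scenario_params
    )
    return ScenarioResult(scenario, current, tailored, icer(current, tailored))


def run_all_scenarios(params: ParameterSet) -> list[ScenarioResult]:
    return [run_scenario(sc, params) for sc in printed_scenarios(params)]


def run_ending_age_variant(end_age: int, params: ParameterSet) -> CEResult:
    """Tailored programme with last screens capped at ``end_age`` (69 or 74)."""
    if end_age not in (69, 74):
        raise ValidationError("ending-age variant supports end_age 69 or 74 only")
    current = run_strategy(build_current_strategy(params.config), params)
    tailored_strategy = truncate_strategy(
        build_tailored_strategy(params.strat, params.config), end_age
    )
    return icer(current, run_strategy(tailored_strategy, params))


def table2_frame(results: list[ScenarioResult]) -> pd.DataFrame:
    """Cost / LY / QALY / increments per scenario, one row per arm."""
    rows = []
    for r in results:
        rows.append(
            {
                "scenario": r.scenario.name,
                "strategy": "current",
                "cost_sgd": r.current.discounted_cost,
                "life_years": r.current.life_years,
                "qalys": r.current.qalys,
                "cases_per_1000": r.current.cases_per_1000,
                "death_probability": r.current.death_probability,
                "delta_cost": None,
                "delta_ly": None,
                "delta_qaly": None,
                "icer": None,
            }
        )
        rows.append(
            {
                "scenario": r.scenario.name,
                "strategy": "tailored",
                "cost_sgd": r.tailored.discounted_cost,
                "life_years": r.tailored.life_years,
                "qalys": r.tailored.qalys,
                "cases_per_1000": r.tailored.cases_per_1000,
                "death_probability": r.tailored.death_probability,
                "delta_cost": r.ce.delta_cost,
                "delta_ly": r.ce.delta_ly,
                "delta_qaly": r.ce.delta_qaly,
                "icer": r.ce.icer,
            }
        )
    return pd.DataFrame(rows)
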