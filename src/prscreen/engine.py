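"""Markov cohort recursion over breast-cancer health states.

States: Healthy, Stage I-IV (absorbing until death), Dead. One-year cycles
from ``start_age`` to ``end_age`` inclusive. A healthy woman is diagnosed in
a cycle with probability

    ASIR(age) x stage proportion x test sensitivity x risk multiplier

at an imaging screen (screened stage distribution), or — depending on the
detection mode — presents clinically at the unscreened stage distribution
(no sensitivity factor) in cycles the screening programme does not cover.
Diagnosed women remain in their stage until death (no remission or stage
progression is modelled); everyone is exposed to a flat all-cause mortality
and diagnosed women additionally to a stage-specific annual breast-cancer
mortality. Rewards (costs, life years, QALYs) are accumulated on
start-of-cycle occupancy and discounted at ``(1+r)^-t`` with t = 0 at entry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    STAGES,
    STATES,
    ParameterSet,
    ValidationError,
    asir_lookup,
)
from .strategies import ScreeningSchedule, Strategy, StrategyArm

__all__ = [
    "StateVector",
    "CohortTrace",
    "ArmOutcomes",
    "InfeasibleParametersError",
    "diagnosis_probability",
    "transition_matrix",
    "run_cohort",
    "accumulate",
    "mix_arms",
    "run_arm",
    "run_strategy",
    "trace_frame",
]

N_STATES = len(STATES)
HEALTHY, DEAD = 0, N_STATES - 1
STAGE_IDX = {s: i + 1 for i, s in enumerate(STAGES)}


class InfeasibleParametersError(ValidationError):
    """Per-cycle exit probabilities from some state exceed 1."""


StateVector = np.ndarray  # occupancy over STATES, sums to 1


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy of one arm's cohort over the horizon.

    ``occupancy[t]`` is the state distribution at the start of cycle ``t``
    (age ``ages[t]``); ``occupancy[-1]`` is the distribution after the final
    transition. ``new_diagnoses[t, s]`` is the cohort proportion entering
    stage ``s`` during cycle ``t``.
    """

    ages: np.ndarray  # (n_cycles,)
    occupancy: np.ndarray  # (n_cycles + 1, N_STATES)
    new_diagnoses: np.ndarray  # (n_cycles, len(STAGES))
    new_deaths: np.ndarray  # (n_cycles,)

    @property
    def n_cycles(self) -> int:
        return len(self.ages)


@dataclass(frozen=True)
class ArmOutcomes:
    """Discounted per-woman outcomes over the horizon."""

    discounted_cost: float
    life_years: float
    qalys: float
    cases_per_1000: float
    death_probability: float

    def validate(self) -> None:
        if self.qalys > self.life_years + 1e-9:
            raise ValidationError("QALYs cannot exceed life years")
        if min(
            self.discounted_cost, self.life_years, self.qalys, self.cases_per_1000
        ) < 0:
            raise ValidationError("outcomes must be non-negative")
        if not 0.0 <= self.death_probability <= 1.0:
            raise ValidationError("death probability outside [0,1]")


def _detection(
    age: int,
    is_screen_cycle: bool,
    in_coverage: bool,
    params: ParameterSet,
) -> str:
    """How cancers can surface this cycle: 'screen', 'clinical' or 'none'."""
    if is_screen_cycle:
        return "screen"
    mode = params.config.detection_mode
    if mode == "screen_plus_interval":
        return "clinical"
    if mode == "screen_plus_preentry" and not in_coverage:
        return "clinical"
    return "none"


def diagnosis_probability(
    age: int,
    stage: str,
    multiplier: float,
    is_screen_cycle: bool,
    params: ParameterSet,
    in_coverage: bool = True,
) -> float:
    """Annual probability that a healthy woman is diagnosed at ``stage``.

    ``is_screen_cycle`` means an imaging screen (mammogram/ultrasound) occurs
    this cycle; self-examination visits do not detect and count as non-screen
    cycles. ``in_coverage`` marks cycles at or after the arm's screening
    coverage start (only consulted under detection_mode=screen_plus_preentry).
    """
    if multiplier < 0:
        raise ValidationError("risk multiplier must be non-negative")
    kind = _detection(age, is_screen_cycle, in_coverage, params)
    if kind == "none":
        return 0.0
    rate = asir_lookup(params.asir, age) * multiplier
    if kind == "screen":
        p = (
            rate
            * params.stage_dist_screened.p_stage[stage]
            * params.config.mammography_sensitivity
        )
    else:
        p = rate * params.stage_dist_unscreened.p_stage[stage]
    return min(1.0, max(0.0, p))


def transition_matrix(
    age: int,
    multiplier: float,
    is_screen_cycle: bool,
    params: ParameterSet,
    in_coverage: bool = True,
) -> np.ndarray:
    """Row-stochastic one-cycle transition matrix over STATES."""
    m = np.zeros((N_STATES, N_STATES))
    q_ac = params.mortality.all_cause

    p_diag = np.array(
        [
            diagnosis_probability(age, s, multiplier, is_screen_cycle, params, in_coverage)
            for s in STAGES
        ]
    )
    exit_mass = p_diag.sum() + q_ac
    if exit_mass > 1.0:
        raise InfeasibleParametersError(
            f"healthy-state exit probability {exit_mass:.4f} > 1 at age {age}"
        )
    m[HEALTHY, 1:-1] = p_diag
    m[HEALTHY, DEAD] = q_ac
    m[HEALTHY, HEALTHY] = 1.0 - exit_mass

    for s in STAGES:
        i = STAGE_IDX[s]
        q = min(1.0, params.mortality.stage_rate[s] + q_ac)
        m[i, DEAD] = q
        m[i, i] = 1.0 - q

    m[DEAD, DEAD] = 1.0
    return m


def run_cohort(
    schedule: ScreeningSchedule,
    multiplier: float,
    params: ParameterSet,
    coverage_start_age: int | None = None,
) -> CohortTrace:
    """Propagate a cohort that starts 100% healthy through the horizon."""
    cfg = params.config
    if coverage_start_age is None:
        coverage_start_age = schedule.first_imaging_age
    if coverage_start_age is None:  # no imaging screens: never covered
        coverage_start_age = cfg.end_age + 1
    ages = np.arange(cfg.start_age, cfg.end_age + 1)
    n = len(ages)
    occ = np.zeros((n + 1, N_STATES))
    occ[0, HEALTHY] = 1.0
    new_diag = np.zeros((n, len(STAGES)))
    new_deaths = np.zeros(n)
    for t, age in enumerate(ages):
        m = transition_matrix(
            int(age),
            multiplier,
            schedule.is_screen_age(int(age)),
            params,
            in_coverage=int(age) >= coverage_start_age,
        )
        new_diag[t] = occ[t, HEALTHY] * m[HEALTHY, 1:-1]
        nxt = occ[t] @ m
        new_deaths[t] = nxt[DEAD] - occ[t, DEAD]
        occ[t + 1] = nxt
    return CohortTrace(ages=ages, occupancy=occ, new_diagnoses=new_diag, new_deaths=new_deaths)


def accumulate(
    trace: CohortTrace,
    schedule: ScreeningSchedule,
    entry_costs: float,
    params: ParameterSet,
) -> ArmOutcomes:
    """Discounted costs, LYs and QALYs for one arm's trace.

    Screening test costs are charged to the healthy (alive, undiagnosed)
    occupancy at each screen age; the stage direct medical cost is charged
    per state-year (``stage_cost_mode="annual"``) or once in the diagnosis
    cycle (``"once_at_diagnosis"``); entry costs land in cycle 0. Cases and
    the lifetime death probability are undiscounted.
    """
    cfg = params.config
    n = trace.n_cycles
    t = np.arange(n)
    disc = (1.0 + cfg.discount_rate) ** (-t)

    # start-of-cycle occupancy, optionally half-cycle corrected
    occ = trace.occupancy
    weight = 0.5 * (occ[:-1] + occ[1:]) if cfg.half_cycle_correction else occ[:-1]

    alive = 1.0 - weight[:, DEAD]
    life_years = float(disc @ alive)

    u = np.array([params.utilities.utility[s] for s in ("Healthy",) + STAGES] + [0.0])
    qalys = float(disc @ (weight @ u))

    stage_cost = np.array([params.costs.stage_cost[s] for s in STAGES])
    if cfg.stage_cost_mode == "annual":
        disease_cost = float(disc @ (weight[:, 1:-1] @ stage_cost))
    else:
        disease_cost = float(disc @ (trace.new_diagnoses @ stage_cost))

    screen_cost = 0.0
    for i, age in enumerate(trace.ages):
        modality = schedule.modality(int(age))
        if modality is not None:
            screen_cost += (
                disc[i] * weight[i, HEALTHY] * params.costs.test_cost[modality]
            )

    total_cost = entry_costs + screen_cost + disease_cost
    out = ArmOutcomes(
        discounted_cost=total_cost,
        life_years=life_years,
        qalys=qalys,
        cases_per_1000=float(trace.new_diagnoses.sum() * 1000.0),
        death_probability=float(trace.occupancy[-1, DEAD]),
    )
    out.validate()
    return out


def mix_arms(results: list[tuple[float, ArmOutcomes]]) -> ArmOutcomes:
    """Population-weighted expectation of per-arm outcomes."""
    weights = [w for w, _ in results]
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValidationError(f"arm weights sum to {sum(weights)!r}, expected 1")
    agg = {
        f: sum(w * getattr(o, f) for w, o in results)
        for f in (
            "discounted_cost",
            "life_years",
            "qalys",
            "cases_per_1000",
            "death_probability",
        )
    }
    return ArmOutcomes(**agg)


def run_arm(arm: StrategyArm, entry_costs: float, params: ParameterSet) -> tuple[
    ArmOutcomes, CohortTrace
]:
    trace = run_cohort(arm.schedule, arm.multiplier, params, arm.coverage_start_age)
    return accumulate(trace, arm.schedule, entry_costs, params), trace


def run_strategy(strategy: Strategy, params: ParameterSet) -> ArmOutcomes:
    """Weighted outcome of a whole programme (all risk-group arms)."""
    strategy.validate()
    entry = strategy.entry_cost(params.costs)
    results = []
    for arm in strategy.arms:
        outcomes, _ = run_arm(arm, entry, params)
        results.append((arm.weight, outcomes))
    return mix_arms(results)


def trace_frame(trace: CohortTrace):
    """Long-format export: one row per (age, state) plus per-age diagnoses."""
    import pandas as pd

    rows = []
    for t, age in enumerate(trace.ages):
        for i, state in enumerate(STATES):
            rows.append(
                {"age": int(age), "state": state, "occupancy": trace.occupancy[t, i]}
            )
    occ = pd.DataFrame(rows, columns=["age", "state", "occupancy"])
    diag = pd.DataFrame(
        trace.new_diagnoses,
        columns=[f"new_diagnoses_{s}" for s in STAGES],
    )
    diag.insert(0, "age", trace.ages.astype(int))
    diag["new_deaths"] = trace.new_deaths
    return occ, diag
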