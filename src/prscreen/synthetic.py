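"""Synthetic parameter sets and an individual-level microsimulation oracle.

``generate_parameter_set`` draws random-but-realistic inputs with the same
statistical structure the analysis assumes — an incidence curve that rises
with age and plateaus, stage simplexes from Dirichlet draws, utilities
non-increasing and costs increasing with stage — so every stage of the
pipeline can be exercised without any external data.

``microsim_oracle`` simulates individual women year by year using the exact
per-cycle transition probabilities of the cohort engine (shared code path)
and the same reward accounting, realized stochastically. Its means converge
to the cohort recursion's expectations, which pins the deterministic engine
against an independent accounting of the same process.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import engine
from .engine import ArmOutcomes
from .parameters import (
    STAGES,
    AgeRateTable,
    CostTable,
    MortalityTable,
    ParameterSet,
    RiskGroup,
    RiskStratification,
    StageDistribution,
    UtilityTable,
    baseline_parameters,
    _default_psa_spec,
    _fill_default_bounds,
)
from .strategies import Strategy

__all__ = ["SyntheticSpec", "generate_parameter_set", "microsim_oracle"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Dispersion knobs for the generator; zero dispersion reproduces the
    baseline fixture exactly."""

    seed: int = 0
    n_age_bands: int = 8  # 5-year bands covering ages 35..74
    incidence_scale_range: tuple[float, float] = (0.7, 1.4)
    stage_dirichlet_concentration: float | None = 60.0
    cost_lognormal_sigma: float = 0.15
    utility_jitter: float = 0.05
    risk_dirichlet_concentration: float | None = 40.0


def _is_degenerate(spec: SyntheticSpec) -> bool:
    return (
        spec.incidence_scale_range == (1.0, 1.0)
        and spec.stage_dirichlet_concentration is None
        and spec.cost_lognormal_sigma == 0.0
        and spec.utility_jitter == 0.0
        and spec.risk_dirichlet_concentration is None
    )


def generate_parameter_set(spec: SyntheticSpec) -> ParameterSet:
    """A validated random parameter set with realistic structure."""
    base = baseline_parameters()
    if _is_degenerate(spec):
        return base
    rng = np.random.default_rng(spec.seed)

    # incidence: scaled baseline-shaped curve, increasing then plateauing
    scale = rng.uniform(*spec.incidence_scale_range)
    n = max(2, spec.n_age_bands)
    lows = 35 + 5 * np.arange(n)
    base_rates = np.array(
        [engine.asir_lookup(base.asir, min(int(a), 74)) for a in lows]
    )
    jitter = rng.lognormal(0.0, 0.10, size=n)
    rates = np.minimum.accumulate((scale * base_rates * jitter)[::-1])[::-1]
    rates = np.maximum.accumulate(np.clip(rates, 1e-6, 0.05))
    bands = [(int(lows[i]), int(lows[i] + 4), float(rates[i])) for i in range(n)]
    bands[-1] = (bands[-1][0], 120, bands[-1][2])
    asir = AgeRateTable(tuple(bands))

    # stage simplexes around the baseline mixes
    def simplex(dist: StageDistribution) -> StageDistribution:
        if spec.stage_dirichlet_concentration is None:
            return dist
        alpha = spec.stage_dirichlet_concentration * np.array(
            [dist.p_stage[s] for s in STAGES]
        )
        draw = rng.dirichlet(np.maximum(alpha, 0.5))
        draw = draw / draw.sum()
        return StageDistribution(dict(zip(STAGES, map(float, draw))), dist.context)

    # mortality: jittered, kept in (0,1)
    mort = MortalityTable(
        stage_rate={
            s: float(np.clip(q * rng.lognormal(0.0, 0.15), 1e-5, 0.9))
            for s, q in base.mortality.stage_rate.items()
        },
        all_cause=float(
            np.clip(base.mortality.all_cause * rng.lognormal(0.0, 0.15), 1e-5, 0.05)
        ),
    )

    # utilities: jittered then sorted so they stay non-increasing with stage
    jit = rng.uniform(-spec.utility_jitter, spec.utility_jitter, size=len(STAGES))
    vals = np.clip(
        np.array([base.utilities.utility[s] for s in STAGES]) + jit, 0.05, 0.98
    )
    vals = np.sort(vals)[::-1]
    utilities = UtilityTable({"Healthy": 1.0, **dict(zip(STAGES, map(float, vals)))})

    # costs: log-normal dispersion, sorted so they increase with stage
    stage_costs = np.array([base.costs.stage_cost[s] for s in STAGES]) * rng.lognormal(
        0.0, spec.cost_lognormal_sigma, size=len(STAGES)
    )
    stage_costs = np.sort(stage_costs)
    test_costs = {
        m: float(c * rng.lognormal(0.0, spec.cost_lognormal_sigma)) if c > 0 else 0.0
        for m, c in base.costs.test_cost.items()
    }
    costs = CostTable(
        stage_cost=dict(zip(STAGES, map(float, stage_costs))), test_cost=test_costs
    )

    # risk-group proportions on the simplex; multipliers stay ordered
    if spec.risk_dirichlet_concentration is None:
        strat = base.strat
    else:
        props = tuple(g.population_proportion for g in base.strat.groups)
        draw = rng.dirichlet(spec.risk_dirichlet_concentration * np.array(props))
        draw = draw / draw.sum()
        cuts = np.cumsum(draw) * 100.0
        cuts[-1] = 100.0
        groups, pct = [], 0.0
        for g, p, hi in zip(base.strat.groups, draw, cuts):
            groups.append(
                RiskGroup(
                    name=g.name,
                    percentile_low=float(pct),
                    percentile_high=float(hi),
                    population_proportion=float(p),
                    risk_multiplier=g.risk_multiplier,
                )
            )
            pct = float(hi)
        strat = RiskStratification(tuple(groups))

    ps = ParameterSet(
        asir=asir,
        stage_dist_screened=simplex(base.stage_dist_screened),
        stage_dist_unscreened=simplex(base.stage_dist_unscreened),
        mortality=mort,
        utilities=utilities,
        costs=costs,
        strat=strat,
        config=base.config,
        osa_bounds={},
    )
    ps = _fill_default_bounds(ps)
    ps = replace(ps, psa_spec=_default_psa_spec(ps))
    ps.validate()
    return ps


def _simulate_arm(
    arm,
    entry_cost: float,
    params: ParameterSet,
    n: int,
    rng: np.random.Generator,
):
    """Vectorized per-woman simulation of one arm; returns per-woman outcome
    arrays (cost, ly, qaly, diagnosed, dead)."""
    cfg = params.config
    ages = np.arange(cfg.start_age, cfg.end_age + 1)
    disc = (1.0 + cfg.discount_rate) ** -(ages - cfg.start_age).astype(float)
    u = np.array(
        [params.utilities.utility[s] for s in ("Healthy",) + STAGES] + [0.0]
    )
    stage_cost = np.array([0.0] + [params.costs.stage_cost[s] for s in STAGES] + [0.0])

    state = np.zeros(n, dtype=np.int8)  # HEALTHY
    cost = np.full(n, float(entry_cost))
    ly = np.zeros(n)
    qaly = np.zeros(n)
    diagnosed = np.zeros(n, dtype=bool)

    for t, age in enumerate(ages):
        m = engine.transition_matrix(
            int(age),
            arm.multiplier,
            arm.schedule.is_screen_age(int(age)),
            params,
            in_coverage=(
                arm.coverage_start_age is not None
                and int(age) >= arm.coverage_start_age
            ),
        )
        # rewards on start-of-cycle state, mirroring the cohort accumulator
        alive = state != engine.DEAD
        healthy = state == engine.HEALTHY
        ly += disc[t] * alive
        qaly += disc[t] * u[state]
        modality = arm.schedule.modality(int(age))
        if modality is not None:
            cost += disc[t] * healthy * params.costs.test_cost[modality]
        if cfg.stage_cost_mode == "annual":
            cost += disc[t] * stage_cost[state]

        # one categorical transition per woman from her state's matrix row
        cum = np.cumsum(m, axis=1)
        draws = rng.random(n)
        new_state = (draws[:, None] > cum[state]).sum(axis=1).astype(np.int8)
        newly_diag = healthy & (new_state > engine.HEALTHY) & (new_state < engine.DEAD)
        if cfg.stage_cost_mode == "once_at_diagnosis":
            cost += disc[t] * newly_diag * stage_cost[new_state]
        diagnosed |= newly_diag
        state = new_state

    dead = state == engine.DEAD
    return cost, ly, qaly, diagnosed, dead


def microsim_oracle(
    strategy: Strategy,
    params: ParameterSet,
    n_individuals: int,
    seed: int = 0,
) -> tuple[ArmOutcomes, dict[str, float]]:
    """Monte-Carlo estimate of a strategy's outcomes with standard errors.

    Women are allocated to risk-group arms multinomially by the arm weights;
    each is simulated year by year with the cohort engine's own transition
    matrices. Returns (mean outcomes, standard error per outcome field).
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    strategy.validate()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_individuals, [a.weight for a in strategy.arms])
    entry = strategy.entry_cost(params.costs)

    parts = []
    for arm, n_arm in zip(strategy.arms, counts):
        if n_arm == 0:
            continue
        parts.append(_simulate_arm(arm, entry, params, int(n_arm), rng))
    cost, ly, qaly, diagnosed, dead = (np.concatenate(cols) for cols in zip(*parts))

    def mean_se(x):
        x = np.asarray(x, dtype=float)
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))

    fields = {
        "discounted_cost": mean_se(cost),
        "life_years": mean_se(ly),
        "qalys": mean_se(qaly),
        "cases_per_1000": mean_se(diagnosed * 1000.0),
        "death_probability": mean_se(dead),
    }
    outcomes = ArmOutcomes(**{k: v[0] for k, v in fields.items()})
    ses = {k: v[1] for k, v in fields.items()}
    return outcomes, ses
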