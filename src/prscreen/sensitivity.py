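"""Parameter-uncertainty analyses: one-way (tornado) and probabilistic.

One-way analysis re-runs the deterministic model with a single parameter at
its lower and upper bound (printed ranges where the source table gives them,
otherwise 80%/120% of baseline) and records the ICER at each bound.

The probabilistic analysis draws cost parameters from moment-matched Gamma
distributions and stage utilities from moment-matched Beta distributions
(printed ranges treated as 95% intervals, sd = half-width / 1.96), re-runs
both programmes per draw with common parameters across arms, and summarizes
decision uncertainty as a cost-effectiveness plane and acceptability curve.

Cost and utility draws do not alter transition probabilities, so each arm's
cohort trace is computed once and the per-draw outcomes are exact linear
functions of the drawn values; ``run_psa`` exploits this, and a test pins the
linear path to a full re-run of the accumulator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import engine
from .cea import CEResult, icer
from .engine import run_cohort
from .parameters import (
    STAGES,
    ParameterSet,
    ValidationError,
    osa_parameter_ids,
    parameter_value,
    set_parameter,
)
from .strategies import Strategy, build_current_strategy, build_tailored_strategy

__all__ = [
    "TornadoEntry",
    "PSADistribution",
    "PSAResult",
    "osa_run",
    "tornado",
    "fit_gamma",
    "fit_beta",
    "build_psa_distributions",
    "run_psa",
    "ceac",
    "wtp_for_certainty",
]

log = logging.getLogger("prscreen")

#: printed ranges are read as 95% intervals when moment-matching
RANGE_Z = 1.96


def default_strategies(params: ParameterSet) -> tuple[Strategy, Strategy]:
    """(reference, comparator) = (current programme, tailored programme)."""
    return (
        build_current_strategy(params.config),
        build_tailored_strategy(params.strat, params.config),
    )


def _evaluate(params: ParameterSet, strategies=None) -> CEResult:
    if strategies is None:
        ref, comp = default_strategies(params)
    else:
        ref, comp = strategies
    return icer(engine.run_strategy(ref, params), engine.run_strategy(comp, params))


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    parameter_id: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def osa_run(parameter_id: str, params: ParameterSet, strategies=None) -> TornadoEntry:
    """ICER with one parameter at each of its one-way bounds.

    When ``strategies`` is None (the default) both programmes are rebuilt
    from the perturbed parameter set, so perturbations of the risk
    multipliers propagate into the tailored arms.
    """
    if parameter_id not in params.osa_bounds:
        raise ValidationError(f"no one-way bounds for parameter {parameter_id!r}")
    low, high = params.osa_bounds[parameter_id]
    results = []
    for bound in (low, high):
        perturbed = set_parameter(params, parameter_id, bound)
        res = _evaluate(perturbed, strategies)
        if res.icer is None:
            raise ValidationError(
                f"ICER undefined at {parameter_id}={bound} ({res.flag})"
            )
        results.append(res.icer)
    return TornadoEntry(
        parameter_id=parameter_id,
        low=low,
        high=high,
        icer_at_low=results[0],
        icer_at_high=results[1],
    )


def tornado(params: ParameterSet, strategies=None) -> list[TornadoEntry]:
    """All one-way entries, sorted by span (descending, ties by id)."""
    entries = [osa_run(pid, params, strategies) for pid in osa_parameter_ids(params)]
    return sorted(entries, key=lambda e: (-e.span, e.parameter_id))


# ---------------------------------------------------------------------------
# distribution fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSADistribution:
    parameter_id: str
    family: str  # "gamma" | "beta"
    mean: float
    low: float
    high: float
    #: fitted parameters: (shape, scale) for gamma, (a, b) for beta;
    #: empty for a degenerate (zero-variance) distribution
    shape_params: tuple[float, ...] = field(default=())

    @property
    def sd(self) -> float:
        if not self.shape_params:
            return 0.0
        if self.family == "gamma":
            k, theta = self.shape_params
            return math.sqrt(k) * theta
        a, b = self.shape_params
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if not self.shape_params:
            return np.full(n, self.mean)
        if self.family == "gamma":
            k, theta = self.shape_params
            return rng.gamma(k, theta, size=n)
        a, b = self.shape_params
        return rng.beta(a, b, size=n)


def fit_gamma(mean: float, low: float, high: float, parameter_id: str = "") -> PSADistribution:
    """Moment-matched Gamma: mean preserved, sd = (high-low)/(2*1.96)."""
    if not (0 < low < mean < high):
        raise ValidationError(
            f"gamma fit needs 0 < low < mean < high, got ({low}, {mean}, {high})"
        )
    sd = (high - low) / (2 * RANGE_Z)
    k = (mean / sd) ** 2
    theta = sd * sd / mean
    return PSADistribution(parameter_id, "gamma", mean, low, high, (k, theta))


def fit_beta(mean: float, low: float, high: float, parameter_id: str = "") -> PSADistribution:
    """Moment-matched Beta on [0,1]; sd shrunk to feasibility when needed."""
    if not 0 < mean < 1:
        raise ValidationError(f"beta fit needs mean in (0,1), got {mean}")
    if not (low < mean < high):
        raise ValidationError(
            f"beta fit needs low < mean < high, got ({low}, {mean}, {high})"
        )
    sd = (high - low) / (2 * RANGE_Z)
    max_var = mean * (1 - mean)
    if sd * sd >= max_var:
        sd = 0.999 * math.sqrt(max_var)
        log.info(
            "beta fit for %s: requested sd infeasible, shrunk to %.4g",
            parameter_id or mean,
            sd,
        )
    nu = mean * (1 - mean) / (sd * sd) - 1
    a, b = mean * nu, (1 - mean) * nu
    return PSADistribution(parameter_id, "beta", mean, low, high, (a, b))


def build_psa_distributions(params: ParameterSet) -> list[PSADistribution]:
    """Distributions for every parameter named in the set's PSA spec."""
    dists = []
    for pid in sorted(params.psa_spec):
        spec = params.psa_spec[pid]
        mean, low, high = spec["mean"], spec["low"], spec["high"]
        if low == high:  # zero-variance: degenerate at the mean
            dists.append(PSADistribution(pid, spec["family"], mean, low, high, ()))
        elif spec["family"] == "gamma":
            dists.append(fit_gamma(mean, low, high, pid))
        elif spec["family"] == "beta":
            dists.append(fit_beta(mean, low, high, pid))
        else:
            raise ValidationError(f"unknown PSA family {spec['family']!r} for {pid}")
    return dists


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSAResult:
    """Per-draw incremental results (comparator minus reference)."""

    delta_cost: np.ndarray  # (n,)
    delta_qaly: np.ndarray  # (n,)
    delta_ly: float  # deterministic: LYs do not depend on varied parameters
    n: int
    seed: int
    parameter_draws: dict[str, np.ndarray]

    def quadrant_fractions(self) -> dict[str, float]:
        se = (self.delta_qaly > 0) & (self.delta_cost <= 0)
        ne = (self.delta_qaly > 0) & (self.delta_cost > 0)
        nw = (self.delta_qaly <= 0) & (self.delta_cost > 0)
        sw = (self.delta_qaly <= 0) & (self.delta_cost <= 0)
        return {
            "SE": float(se.mean()),
            "NE": float(ne.mean()),
            "NW": float(nw.mean()),
            "SW": float(sw.mean()),
        }


@dataclass(frozen=True)
class _RewardBases:
    """Discounted reward aggregates of one arm's (fixed) cohort trace.

    cost(draw) = Σ_s stage_cost_s · disease_base_s
               + Σ_m test_cost_m · (screen_base_m + entry_m)
    qaly(draw) = healthy_base + Σ_s utility_s · state_base_s
    """

    weight: float
    life_years: float
    healthy_base: float
    state_base: dict[str, float]
    disease_base: dict[str, float]
    screen_base: dict[str, float]
    entry_items: tuple[str, ...]
    cases_per_1000: float
    death_probability: float


def _reward_bases(strategy: Strategy, params: ParameterSet) -> list[_RewardBases]:
    cfg = params.config
    t = np.arange(cfg.n_cycles)
    disc = (1.0 + cfg.discount_rate) ** (-t)
    bases = []
    for arm in strategy.arms:
        trace = run_cohort(arm.schedule, arm.multiplier, params, arm.coverage_start_age)
        occ = trace.occupancy
        w = 0.5 * (occ[:-1] + occ[1:]) if cfg.half_cycle_correction else occ[:-1]
        state_base = {
            s: float(disc @ w[:, engine.STAGE_IDX[s]]) for s in STAGES
        }
        if cfg.stage_cost_mode == "annual":
            disease_base = dict(state_base)
        else:
            disease_base = {
                s: float(disc @ trace.new_diagnoses[:, i]) for i, s in enumerate(STAGES)
            }
        screen_base: dict[str, float] = {}
        for i, age in enumerate(trace.ages):
            modality = arm.schedule.modality(int(age))
            if modality is not None:
                screen_base[modality] = screen_base.get(modality, 0.0) + float(
                    disc[i] * w[i, engine.HEALTHY]
                )
        bases.append(
            _RewardBases(
                weight=arm.weight,
                life_years=float(disc @ (1.0 - w[:, engine.DEAD])),
                healthy_base=float(disc @ w[:, engine.HEALTHY]),
                state_base=state_base,
                disease_base=disease_base,
                screen_base=screen_base,
                entry_items=strategy.entry_items,
                cases_per_1000=float(trace.new_diagnoses.sum() * 1000.0),
                death_probability=float(trace.occupancy[-1, engine.DEAD]),
            )
        )
    return bases


def _strategy_draw_outcomes(
    bases: list[_RewardBases],
    draws: dict[str, np.ndarray],
    params: ParameterSet,
    n: int,
) -> tuple[np.ndarray, np.ndarray, float]:
    """(cost, qaly) arrays over draws plus the fixed mixed LY."""

    def value(pid: str, fallback: float) -> np.ndarray:
        return draws.get(pid, np.full(n, fallback))

    cost = np.zeros(n)
    qaly = np.zeros(n)
    ly = 0.0
    for b in bases:
        arm_cost = np.zeros(n)
        for s in STAGES:
            arm_cost += value(f"stage_cost.{s}", params.costs.stage_cost[s]) * b.disease_base[s]
        for m, base in b.screen_base.items():
            arm_cost += value(f"test_cost.{m}", params.costs.test_cost[m]) * base
        for item in b.entry_items:
            arm_cost += value(f"test_cost.{item}", params.costs.test_cost[item])
        arm_qaly = np.full(n, b.healthy_base)
        for s in STAGES:
            arm_qaly = arm_qaly + value(f"utility.{s}", params.utilities.utility[s]) * b.state_base[s]
        cost += b.weight * arm_cost
        qaly += b.weight * arm_qaly
        ly += b.weight * b.life_years
    return cost, qaly, ly


def run_psa(
    params: ParameterSet,
    strategies: tuple[Strategy, Strategy] | None = None,
    n: int = 10_000,
    seed: int = 0,
) -> PSAResult:
    """Monte Carlo over the PSA distributions, common draws across arms.

    One independent random substream per parameter (derived deterministically
    from ``seed`` and the sorted parameter ids), so results do not depend on
    evaluation order.
    """
    if n <= 0:
        raise ValidationError("number of PSA draws must be positive")
    if strategies is None:
        strategies = default_strategies(params)
    reference, comparator = strategies

    dists = build_psa_distributions(params)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(dists))
    draws = {
        d.parameter_id: d.sample(np.random.default_rng(child), n)
        for d, child in zip(dists, children)
    }

    ref_bases = _reward_bases(reference, params)
    comp_bases = _reward_bases(comparator, params)
    ref_cost, ref_qaly, ref_ly = _strategy_draw_outcomes(ref_bases, draws, params, n)
    comp_cost, comp_qaly, comp_ly = _strategy_draw_outcomes(comp_bases, draws, params, n)

    return PSAResult(
        delta_cost=comp_cost - ref_cost,
        delta_qaly=comp_qaly - ref_qaly,
        delta_ly=comp_ly - ref_ly,
        n=n,
        seed=seed,
        parameter_draws=draws,
    )


def ceac(psa: PSAResult, wtp_grid) -> list[tuple[float, float]]:
    """P(comparator cost-effective) = P(wtp·ΔQALY − ΔC ≥ 0) per threshold."""
    if psa.n < 1:
        raise ValidationError("PSA has no draws")
    out = []
    for wtp in wtp_grid:
        p = float((wtp * psa.delta_qaly - psa.delta_cost >= 0).mean())
        out.append((float(wtp), p))
    return out


def wtp_for_certainty(psa: PSAResult) -> float:
    """Smallest WTP at which the acceptability curve reaches 1.0.

    With every draw at ΔQALY > 0 this is max(0, max ΔC/ΔQALY); if some draw
    has ΔQALY ≤ 0 with ΔC > 0 no finite threshold achieves certainty.
    """
    bad = (psa.delta_qaly <= 0) & (psa.delta_cost > 0)
    if bad.any():
        return math.inf
    ok = psa.delta_qaly > 0
    lower = float(np.max(psa.delta_cost[ok] / psa.delta_qaly[ok])) if ok.any() else 0.0
    lower = max(0.0, lower)
    # draws with ΔQALY < 0 and ΔC ≤ 0 stop being acceptable above ΔC/ΔQALY
    neg = psa.delta_qaly < 0
    if neg.any():
        upper = float(np.min(psa.delta_cost[neg] / psa.delta_qaly[neg]))
        if lower > upper:
            return math.inf
    return lower
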