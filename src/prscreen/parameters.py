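"""Typed model inputs: validation, I/O, and the bundled baseline parameter set.

The model is driven entirely by a :class:`ParameterSet` — an age-specific
incidence curve, stage distributions at detection (screened vs unscreened
route), stage-specific annual breast-cancer mortality, a flat all-cause
mortality rate, stage utilities, direct medical and test costs, the
polygenic-risk stratification (population proportions and relative-risk
multipliers), and run configuration. The baseline values are bundled as a
YAML fixture inside the package and never fetched.
"""

from __future__ import annotations

import copy
import importlib.resources
import logging
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "STAGES",
    "STATES",
    "ValidationError",
    "ParseError",
    "AgeRateTable",
    "StageDistribution",
    "MortalityTable",
    "UtilityTable",
    "CostTable",
    "RiskGroup",
    "RiskStratification",
    "ModelConfig",
    "ParameterSet",
    "baseline_parameters",
    "load_parameters",
    "write_parameters",
    "asir_lookup",
    "parameter_value",
    "set_parameter",
    "osa_parameter_ids",
]

log = logging.getLogger("prscreen")

STAGES = ("I", "II", "III", "IV")
STATES = ("Healthy", "I", "II", "III", "IV", "Dead")

SIMPLEX_TOL = 1e-9

DETECTION_MODES = ("screen_only", "screen_plus_interval", "screen_plus_preentry")
STAGE_COST_MODES = ("annual", "once_at_diagnosis")

#: parameters whose one-way bounds default to 80%/120% of baseline when the
#: fixture does not print an explicit range
_OSA_RULE = 0.80, 1.20


class ValidationError(ValueError):
    """An invariant of the parameter set does not hold."""


class ParseError(ValueError):
    """A parameter file could not be interpreted."""


# ---------------------------------------------------------------------------
# component tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeRateTable:
    """Piecewise-constant annual rate over contiguous, inclusive age bands."""

    bands: tuple[tuple[int, int, float], ...]

    def validate(self, cover_low: int = 35, cover_high: int = 74) -> None:
        if not self.bands:
            raise ValidationError("age-rate table has no bands")
        prev_high = None
        for low, high, rate in self.bands:
            if low > high:
                raise ValidationError(f"band ({low},{high}) has low > high")
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"rate {rate} outside [0,1] in band ({low},{high})")
            if prev_high is not None and low != prev_high + 1:
                raise ValidationError(
                    f"bands not contiguous: gap/overlap between {prev_high} and {low}"
                )
            prev_high = high
        if self.bands[0][0] > cover_low or self.bands[-1][1] < cover_high:
            raise ValidationError(
                f"bands cover [{self.bands[0][0]},{self.bands[-1][1]}], "
                f"need at least [{cover_low},{cover_high}]"
            )


def asir_lookup(asir: AgeRateTable, age: int) -> float:
    """Annual incidence probability for the band containing ``age``."""
    for low, high, rate in asir.bands:
        if low <= age <= high:
            return rate
    raise ValidationError(f"age {age} outside covered bands")


@dataclass(frozen=True)
class StageDistribution:
    """Stage-at-detection simplex for one detection route."""

    p_stage: dict[str, float]
    context: str  # "screened" | "unscreened"

    def validate(self) -> None:
        if set(self.p_stage) != set(STAGES):
            raise ValidationError(f"stage distribution must cover stages {STAGES}")
        for s, p in self.p_stage.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"stage {s} proportion {p} outside [0,1]")
        total = sum(self.p_stage.values())
        if abs(total - 1.0) > SIMPLEX_TOL:
            raise ValidationError(
                f"{self.context} stage proportions sum to {total!r}, expected 1"
            )


@dataclass(frozen=True)
class MortalityTable:
    stage_rate: dict[str, float]
    all_cause: float

    def validate(self) -> None:
        for s in STAGES:
            q = self.stage_rate.get(s)
            if q is None or not 0.0 <= q <= 1.0:
                raise ValidationError(f"stage {s} mortality {q!r} outside [0,1]")
        if not 0.0 <= self.all_cause <= 1.0:
            raise ValidationError(f"all-cause rate {self.all_cause} outside [0,1]")


@dataclass(frozen=True)
class UtilityTable:
    utility: dict[str, float]  # Healthy + stages; Dead implicitly 0

    def validate(self, strict: bool = True) -> None:
        for state in ("Healthy",) + STAGES:
            u = self.utility.get(state)
            if u is None or not 0.0 <= u <= 1.0:
                raise ValidationError(f"utility for {state} is {u!r}, outside [0,1]")
        if strict:
            if self.utility["Healthy"] != 1.0:
                raise ValidationError("Healthy utility must be 1.0")
            seq = [self.utility[s] for s in STAGES]
            if any(a < b for a, b in zip(seq, seq[1:])):
                raise ValidationError("utilities must be non-increasing with stage")


@dataclass(frozen=True)
class CostTable:
    stage_cost: dict[str, float]
    test_cost: dict[str, float]

    def validate(self) -> None:
        for s in STAGES:
            c = self.stage_cost.get(s)
            if c is None or c < 0:
                raise ValidationError(f"stage {s} cost {c!r} must be >= 0")
        for m, c in self.test_cost.items():
            if c < 0:
                raise ValidationError(f"test cost {m}={c} must be >= 0")


@dataclass(frozen=True)
class RiskGroup:
    name: str
    percentile_low: float
    percentile_high: float
    population_proportion: float
    risk_multiplier: float


@dataclass(frozen=True)
class RiskStratification:
    groups: tuple[RiskGroup, ...]

    def validate(self) -> None:
        total = sum(g.population_proportion for g in self.groups)
        if abs(total - 1.0) > SIMPLEX_TOL:
            raise ValidationError(f"group proportions sum to {total!r}, expected 1")
        pct = 0.0
        for g in self.groups:
            if g.risk_multiplier <= 0:
                raise ValidationError(f"group {g.name} multiplier must be > 0")
            if g.percentile_low != pct:
                raise ValidationError("percentile ranges must partition [0,100)")
            pct = g.percentile_high
        if pct != 100:
            raise ValidationError("percentile ranges must end at 100")

    def group(self, name: str) -> RiskGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)


@dataclass(frozen=True)
class ModelConfig:
    start_age: int = 35
    end_age: int = 74
    cycle_length: int = 1
    discount_rate: float = 0.03
    mammography_sensitivity: float = 0.8
    # how cancers surface outside screen visits:
    #   screen_only            detection only at imaging screens
    #   screen_plus_interval   clinical presentation (unscreened stage mix,
    #                          no sensitivity factor) in every non-screen cycle
    #   screen_plus_preentry   clinical presentation only in cycles before the
    #                          arm's screening coverage begins (default; the
    #                          only convention under which screening can be
    #                          both cheaper and more effective, see docs)
    detection_mode: str = "screen_plus_preentry"
    # stage direct-medical-cost accrual: per state-year ("annual") or once at
    # the diagnosis cycle ("once_at_diagnosis")
    stage_cost_mode: str = "annual"
    half_cycle_correction: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValidationError(f"discount rate {self.discount_rate} outside [0,1)")
        if self.start_age >= self.end_age:
            raise ValidationError("start_age must be < end_age")
        if not 0.0 < self.mammography_sensitivity <= 1.0:
            raise ValidationError("sensitivity must be in (0,1]")
        if self.detection_mode not in DETECTION_MODES:
            raise ValidationError(f"unknown detection_mode {self.detection_mode!r}")
        if self.stage_cost_mode not in STAGE_COST_MODES:
            raise ValidationError(f"unknown stage_cost_mode {self.stage_cost_mode!r}")
        if self.cycle_length != 1:
            raise ValidationError("only annual cycles are supported")

    @property
    def n_cycles(self) -> int:
        return self.end_age - self.start_age + 1


# ---------------------------------------------------------------------------
# the full parameter set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterSet:
    asir: AgeRateTable
    stage_dist_screened: StageDistribution
    stage_dist_unscreened: StageDistribution
    mortality: MortalityTable
    utilities: UtilityTable
    costs: CostTable
    strat: RiskStratification
    config: ModelConfig = field(default_factory=ModelConfig)
    #: parameter_id -> (low, high) for one-way sensitivity analysis
    osa_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: parameter_id -> {"family", "mean", "low", "high"} for the PSA
    psa_spec: dict[str, dict] = field(default_factory=dict)

    def validate(self, strict: bool = True) -> None:
        self.asir.validate(self.config.start_age, self.config.end_age)
        self.stage_dist_screened.validate()
        self.stage_dist_unscreened.validate()
        self.mortality.validate()
        self.utilities.validate(strict=strict)
        self.costs.validate()
        self.strat.validate()
        self.config.validate()
        for pid in list(self.osa_bounds) + list(self.psa_spec):
            parameter_value(self, pid)  # raises on unknown ids

    def replace_config(self, **kwargs) -> "ParameterSet":
        return replace(self, config=replace(self.config, **kwargs))


# ---------------------------------------------------------------------------
# flat parameter addressing (used by the sensitivity analyses)
# ---------------------------------------------------------------------------


def parameter_value(params: ParameterSet, pid: str) -> float:
    """Read a scalar model input by dotted id, e.g. ``stage_cost.II``."""
    head, _, rest = pid.partition(".")
    try:
        if head == "stage_cost":
            return params.costs.stage_cost[rest]
        if head == "test_cost":
            return params.costs.test_cost[rest]
        if head == "utility":
            return params.utilities.utility[rest]
        if head == "mortality":
            return params.mortality.stage_rate[rest]
        if head == "stage_dist":
            ctx, _, stage = rest.partition(".")
            dist = (
                params.stage_dist_screened
                if ctx == "screened"
                else params.stage_dist_unscreened
            )
            return dist.p_stage[stage]
        if head == "risk_multiplier":
            return params.strat.group(rest).risk_multiplier
        if pid == "sensitivity":
            return params.config.mammography_sensitivity
        if pid == "discount_rate":
            return params.config.discount_rate
        if pid == "all_cause_mortality":
            return params.mortality.all_cause
    except KeyError:
        pass
    raise ValidationError(f"unknown parameter id {pid!r}")


def set_parameter(params: ParameterSet, pid: str, value: float) -> ParameterSet:
    """Return a copy of ``params`` with one scalar input replaced.

    Probability-type parameters are clamped to their support (utilities and
    sensitivity at 1.0), and perturbing one proportion of a stage simplex
    renormalizes the whole simplex. Strict cross-parameter invariants (stage
    monotonicity of utilities) are not re-imposed: a one-way perturbation is
    allowed to break them.
    """
    parameter_value(params, pid)  # existence check
    head, _, rest = pid.partition(".")
    if head == "stage_cost":
        sc = {**params.costs.stage_cost, rest: max(0.0, value)}
        return replace(params, costs=replace(params.costs, stage_cost=sc))
    if head == "test_cost":
        tc = {**params.costs.test_cost, rest: max(0.0, value)}
        return replace(params, costs=replace(params.costs, test_cost=tc))
    if head == "utility":
        u = {**params.utilities.utility, rest: min(1.0, max(0.0, value))}
        return replace(params, utilities=UtilityTable(u))
    if head == "mortality":
        mr = {**params.mortality.stage_rate, rest: min(1.0, max(0.0, value))}
        return replace(params, mortality=replace(params.mortality, stage_rate=mr))
    if pid == "all_cause_mortality":
        return replace(
            params, mortality=replace(params.mortality, all_cause=min(1.0, max(0.0, value)))
        )
    if head == "stage_dist":
        ctx, _, stage = rest.partition(".")
        attr = "stage_dist_screened" if ctx == "screened" else "stage_dist_unscreened"
        dist: StageDistribution = getattr(params, attr)
        p = {**dist.p_stage, stage: min(1.0, max(0.0, value))}
        total = sum(p.values())
        p = {s: v / total for s, v in p.items()}
        return replace(params, **{attr: StageDistribution(p, dist.context)})
    if head == "risk_multiplier":
        groups = tuple(
            replace(g, risk_multiplier=value) if g.name == rest else g
            for g in params.strat.groups
        )
        return replace(params, strat=RiskStratification(groups))
    if pid == "sensitivity":
        return params.replace_config(mammography_sensitivity=min(1.0, max(1e-12, value)))
    if pid == "discount_rate":
        return params.replace_config(discount_rate=max(0.0, value))
    raise ValidationError(f"unknown parameter id {pid!r}")  # pragma: no cover


def osa_parameter_ids(params: ParameterSet) -> list[str]:
    """Deterministically ordered list of parameters varied one-way."""
    ids: list[str] = []
    ids += [f"risk_multiplier.{g.name}" for g in params.strat.groups]
    ids.append("sensitivity")
    ids += [f"stage_cost.{s}" for s in STAGES]
    ids += [
        f"test_cost.{m}"
        for m in ("mammogram", "ultrasound", "buccal_swab", "questionnaire")
    ]
    ids += [f"utility.{s}" for s in STAGES]
    ids += [f"stage_dist.screened.{s}" for s in STAGES]
    ids += [f"stage_dist.unscreened.{s}" for s in STAGES]
    ids += [f"mortality.{s}" for s in STAGES]
    ids.append("discount_rate")
    return ids


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _params_from_mapping(doc: dict, origin: str) -> ParameterSet:
    try:
        bands = tuple((int(lo), int(hi), float(r)) for lo, hi, r in doc["asir"]["bands"])
        sd = doc["stage_distribution"]
        cfg = doc.get("config", {})
        groups = tuple(
            RiskGroup(
                name=g["name"],
                percentile_low=float(g["percentile_low"]),
                percentile_high=float(g["percentile_high"]),
                population_proportion=float(g["population_proportion"]),
                risk_multiplier=float(g["risk_multiplier"]),
            )
            for g in doc["risk_stratification"]["groups"]
        )
        ps = ParameterSet(
            asir=AgeRateTable(bands),
            stage_dist_screened=StageDistribution(
                {s: float(p) for s, p in sd["screened"].items()}, "screened"
            ),
            stage_dist_unscreened=StageDistribution(
                {s: float(p) for s, p in sd["unscreened"].items()}, "unscreened"
            ),
            mortality=MortalityTable(
                stage_rate={s: float(q) for s, q in doc["mortality"]["stage"].items()},
                all_cause=float(doc["mortality"]["all_cause"]),
            ),
            utilities=UtilityTable({s: float(u) for s, u in doc["utilities"].items()}),
            costs=CostTable(
                stage_cost={s: float(c) for s, c in doc["costs"]["stage"].items()},
                test_cost={m: float(c) for m, c in doc["costs"]["test"].items()},
            ),
            strat=RiskStratification(groups),
            config=ModelConfig(**cfg),
            osa_bounds={
                pid: (float(lo), float(hi))
                for pid, (lo, hi) in doc.get("osa_bounds", {}).items()
            },
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise ParseError(f"malformed parameter document {origin}: {exc!r}") from exc
    except ValueError as exc:
        if isinstance(exc, ValidationError):
            raise
        raise ParseError(f"malformed parameter document {origin}: {exc!r}") from exc
    ps = _fill_default_bounds(ps)
    ps = replace(ps, psa_spec=_default_psa_spec(ps))
    ps.validate()
    return ps


def _fill_default_bounds(params: ParameterSet) -> ParameterSet:
    """Apply the 80%/120% rule to parameters without printed OSA ranges."""
    bounds = dict(params.osa_bounds)
    for pid in osa_parameter_ids(params):
        if pid not in bounds:
            v = parameter_value(params, pid)
            bounds[pid] = (v * _OSA_RULE[0], v * _OSA_RULE[1])
    return replace(params, osa_bounds=bounds)


def _default_psa_spec(params: ParameterSet) -> dict[str, dict]:
    """Probabilistic distributions: Gamma for costs (printed +/-30% ranges),
    Beta for stage utilities (+/-0.1 around the mean). Only cost and utility
    parameters vary probabilistically; everything else is PSA-fixed."""
    spec: dict[str, dict] = {}
    for s in STAGES:
        pid = f"stage_cost.{s}"
        m = params.costs.stage_cost[s]
        lo, hi = params.osa_bounds.get(pid, (0.7 * m, 1.3 * m))
        spec[pid] = {"family": "gamma", "mean": m, "low": lo, "high": hi}
    for t in ("mammogram", "ultrasound", "buccal_swab", "questionnaire"):
        pid = f"test_cost.{t}"
        m = params.costs.test_cost[t]
        if m <= 0:
            continue
        lo, hi = params.osa_bounds.get(pid, (0.7 * m, 1.3 * m))
        spec[pid] = {"family": "gamma", "mean": m, "low": lo, "high": hi}
    for s in STAGES:
        m = params.utilities.utility[s]
        spec[f"utility.{s}"] = {
            "family": "beta",
            "mean": m,
            "low": max(1e-6, m - 0.1),
            "high": min(1.0 - 1e-6, m + 0.1),
        }
    return spec


def _baseline_doc() -> dict:
    text = (
        importlib.resources.files("prscreen").joinpath("data/baseline.yaml").read_text()
    )
    return yaml.safe_load(text)


_BASELINE_CACHE: ParameterSet | None = None


def baseline_parameters() -> ParameterSet:
    """The bundled baseline parameter set (validated)."""
    global _BASELINE_CACHE
    if _BASELINE_CACHE is None:
        _BASELINE_CACHE = _params_from_mapping(_baseline_doc(), "<bundled baseline>")
    return _BASELINE_CACHE


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_parameters(source) -> ParameterSet:
    """Load a parameter set from a YAML file path or mapping.

    Fields absent from ``source`` fall back to the bundled baseline (a notice
    is logged). An ``asir_table`` key may point to a delimited file with
    columns age_low, age_high, rate.
    """
    if isinstance(source, dict):
        doc, origin = copy.deepcopy(source), "<mapping>"
    else:
        origin = str(source)
        with open(source) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ParseError(f"{origin}: top level must be a mapping")
    table_path = doc.pop("asir_table", None)
    if table_path is not None:
        doc["asir"] = {"bands": _read_asir_table(table_path)}
    base = _baseline_doc()
    missing = [k for k in base if k not in doc]
    if missing:
        log.info("parameters %s: using baseline values for %s", origin, ", ".join(missing))
    return _params_from_mapping(_deep_merge(base, doc), origin)


def _read_asir_table(path) -> list[list[float]]:
    import pandas as pd

    try:
        df = pd.read_csv(path)
        return df[["age_low", "age_high", "rate"]].values.tolist()
    except (KeyError, ValueError, OSError) as exc:
        raise ParseError(f"malformed age-rate table {path}: {exc}") from exc


def write_parameters(params: ParameterSet, path) -> None:
    """Serialize a parameter set to YAML (round-trips through ``load_parameters``)."""
    doc = {
        "asir": {"bands": [list(b) for b in params.asir.bands]},
        "stage_distribution": {
            "screened": dict(params.stage_dist_screened.p_stage),
            "unscreened": dict(params.stage_dist_unscreened.p_stage),
        },
        "mortality": {
            "stage": dict(params.mortality.stage_rate),
            "all_cause": params.mortality.all_cause,
        },
        "utilities": dict(params.utilities.utility),
        "costs": {
            "stage": dict(params.costs.stage_cost),
            "test": dict(params.costs.test_cost),
        },
        "risk_stratification": {
            "groups": [
                {
                    "name": g.name,
                    "percentile_low": g.percentile_low,
                    "percentile_high": g.percentile_high,
                    "population_proportion": g.population_proportion,
                    "risk_multiplier": g.risk_multiplier,
                }
                for g in params.strat.groups
            ]
        },
        "config": {
            "start_age": params.config.start_age,
            "end_age": params.config.end_age,
            "cycle_length": params.config.cycle_length,
            "discount_rate": params.config.discount_rate,
            "mammography_sensitivity": params.config.mammography_sensitivity,
            "detection_mode": params.config.detection_mode,
            "stage_cost_mode": params.config.stage_cost_mode,
            "half_cycle_correction": params.config.half_cycle_correction,
        },
        "osa_bounds": {pid: list(b) for pid, b in params.osa_bounds.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
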