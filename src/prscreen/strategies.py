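"""The two comparator screening programmes as explicit per-arm schedules.

The current national programme screens by mammogram every two years from age
50 to 69 (last screen at 68). The risk-tailored programme genotypes every
woman at entry (buccal swab + risk-factor questionnaire, charged once),
stratifies her into a low/intermediate/high PRS group, and screens each group
at its own frequency up to the stated last-screen age (73 for low, 74 for
intermediate and high). The modality offered at a given age follows
conventional age indications: self-examination below 40, ultrasound for
40-49, mammogram from 50.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .parameters import (
    CostTable,
    ModelConfig,
    RiskStratification,
    ValidationError,
)

__all__ = [
    "ScreeningSchedule",
    "StrategyArm",
    "Strategy",
    "modality_for_age",
    "build_current_strategy",
    "build_tailored_strategy",
    "DEFAULT_INTERVALS",
]

IMAGING_MODALITIES = ("mammogram", "ultrasound")

#: screens per group: annual for high risk, biennial for intermediate,
#: triennial for low — chosen so last screens land on ages 74/74/73
DEFAULT_INTERVALS = {"high": 1, "intermediate": 2, "low": 3}
_LAST_SCREEN_AGE = {"high": 74, "intermediate": 74, "low": 73}


def modality_for_age(age: int) -> str:
    """Screening modality indicated at a given age."""
    if age < 40:
        return "self_exam"
    if age < 50:
        return "ultrasound"
    return "mammogram"


@dataclass(frozen=True)
class ScreeningSchedule:
    screen_ages: tuple[int, ...]
    modality_by_age: dict[int, str]

    def validate(self, config: ModelConfig) -> None:
        for a in self.screen_ages:
            if not config.start_age <= a <= config.end_age:
                raise ValidationError(f"screen age {a} outside horizon")
            if a not in self.modality_by_age:
                raise ValidationError(f"screen age {a} has no modality")

    def modality(self, age: int) -> str | None:
        return self.modality_by_age.get(age) if age in self.screen_ages else None

    def is_screen_age(self, age: int) -> bool:
        """True when an imaging screen (capable of detection) happens at ``age``."""
        return self.modality(age) in IMAGING_MODALITIES

    @property
    def first_imaging_age(self) -> int | None:
        """Age of the first detection-capable (imaging) screen, if any."""
        ages = [a for a in self.screen_ages if self.modality_by_age[a] in IMAGING_MODALITIES]
        return min(ages) if ages else None


@dataclass(frozen=True)
class StrategyArm:
    name: str
    weight: float
    multiplier: float
    schedule: ScreeningSchedule
    #: age from which the arm counts as covered by a detection-capable
    #: programme (its first imaging screen); under
    #: detection_mode=screen_plus_preentry, cancers before this age present
    #: clinically at the unscreened stage distribution. Self-examination
    #: visits carry no detection and do not start coverage.
    coverage_start_age: int | None


@dataclass(frozen=True)
class Strategy:
    name: str
    arms: tuple[StrategyArm, ...]
    #: test items charged once per woman at entry (cycle 0)
    entry_items: tuple[str, ...] = ()
    uses_screened_distribution_at_screens: bool = True

    def validate(self) -> None:
        total = sum(a.weight for a in self.arms)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"arm weights sum to {total!r}, expected 1")

    def entry_cost(self, costs: CostTable) -> float:
        return sum(costs.test_cost[item] for item in self.entry_items)


def _schedule(ages: list[int]) -> ScreeningSchedule:
    return ScreeningSchedule(
        screen_ages=tuple(ages),
        modality_by_age={a: modality_for_age(a) for a in ages},
    )


def build_current_strategy(config: ModelConfig) -> Strategy:
    """Biennial mammogram-only screening, ages 50-68 (10 screens)."""
    last = min(68, config.end_age)
    sched = _schedule(list(range(50, last + 1, 2)))
    strategy = Strategy(
        name="current",
        arms=(
            StrategyArm(
                name="all",
                weight=1.0,
                multiplier=1.0,
                schedule=sched,
                coverage_start_age=sched.first_imaging_age,
            ),
        ),
        entry_items=(),
    )
    strategy.validate()
    return strategy


def build_tailored_strategy(
    strat: RiskStratification,
    config: ModelConfig,
    intervals: dict[str, int] | None = None,
    last_screen_age: dict[str, int] | None = None,
) -> Strategy:
    """Polygenic-risk-tailored screening with per-group frequencies.

    Each group's first screen is offset so that, at the default intervals,
    the last screen lands exactly on its stated last-screen age (74 for high
    and intermediate, 73 for low). All women enter the programme at
    ``config.start_age`` (genotyping happens then), so coverage starts at
    entry for every group.
    """
    intervals = dict(DEFAULT_INTERVALS if intervals is None else intervals)
    last_ages = dict(_LAST_SCREEN_AGE if last_screen_age is None else last_screen_age)
    arms = []
    for group in strat.groups:
        step = intervals[group.name]
        first = config.start_age + (step - 1)
        last = min(last_ages.get(group.name, config.end_age), config.end_age)
        sched = _schedule(list(range(first, last + 1, step)))
        arms.append(
            StrategyArm(
                name=group.name,
                weight=group.population_proportion,
                multiplier=group.risk_multiplier,
                schedule=sched,
                coverage_start_age=sched.first_imaging_age,
            )
        )
    strategy = Strategy(
        name="tailored",
        arms=tuple(arms),
        entry_items=("buccal_swab", "questionnaire"),
    )
    strategy.validate()
    return strategy


def truncate_strategy(strategy: Strategy, end_age: int) -> Strategy:
    """Drop screens after ``end_age`` (used by the ending-age scenario)."""
    arms = tuple(
        replace(
            arm,
            schedule=_schedule([a for a in arm.schedule.screen_ages if a <= end_age]),
        )
        for arm in strategy.arms
    )
    return replace(strategy, arms=arms)
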