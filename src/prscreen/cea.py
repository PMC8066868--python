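"""Incremental cost-effectiveness: ICER, plane quadrant, dominance, NMB."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .engine import ArmOutcomes
from .parameters import ValidationError

__all__ = ["CEResult", "icer", "nmb"]


@dataclass(frozen=True)
class CEResult:
    """Comparator-minus-reference increments on the cost-effectiveness plane.

    ``icer`` is ΔC/ΔQALY (signed; a negative ICER in the SE quadrant means
    the comparator is cheaper and more effective, i.e. dominant). When
    ΔQALY = 0 the ratio is undefined and ``flag`` says why.
    """

    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer: float | None
    quadrant: str  # NE | SE | SW | NW | origin
    dominance: str  # comparator_dominates | reference_dominates | trade_off | equivalent
    flag: str | None = None


def _quadrant(delta_qaly: float, delta_cost: float) -> str:
    if delta_qaly == 0 and delta_cost == 0:
        return "origin"
    if delta_qaly > 0:
        return "SE" if delta_cost <= 0 else "NE"
    if delta_qaly < 0:
        return "NW" if delta_cost >= 0 else "SW"
    # ΔQALY == 0, ΔC != 0: sits on the vertical axis; attribute by cost sign
    return "SE" if delta_cost < 0 else "NE"


def icer(reference: ArmOutcomes, comparator: ArmOutcomes) -> CEResult:
    """Incremental result of ``comparator`` against ``reference``."""
    dc = comparator.discounted_cost - reference.discounted_cost
    dly = comparator.life_years - reference.life_years
    dq = comparator.qalys - reference.qalys

    flag = None
    if dq == 0 and dc == 0 and dly == 0:
        ratio = None
        flag = "equivalent"
    elif dq == 0:
        ratio = None
        flag = "undefined_cost_" + ("saving" if dc < 0 else "increasing")
    else:
        ratio = dc / dq

    quad = _quadrant(dq, dc)
    if flag == "equivalent":
        dominance = "equivalent"
    elif quad == "SE":
        dominance = "comparator_dominates"
    elif quad == "NW":
        dominance = "reference_dominates"
    else:
        dominance = "trade_off"
    return CEResult(
        delta_cost=dc,
        delta_ly=dly,
        delta_qaly=dq,
        icer=ratio,
        quadrant=quad,
        dominance=dominance,
        flag=flag,
    )


def nmb(outcomes: ArmOutcomes, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold (SGD/QALY)."""
    if wtp < 0 or not math.isfinite(wtp):
        raise ValidationError("willingness-to-pay must be a finite value >= 0")
    return wtp * outcomes.qalys - outcomes.discounted_cost
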