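"""Cost-effectiveness engine: ratios, total management cost, ICER,
cost-effectiveness-plane quadrant and GDP-per-capita threshold class.

The incremental cost-effectiveness ratio compares the new strategy
against the comparator at the cohort level:

    ICER = ΔC / ΔE = (C_new − C_comp) / (E_new − E_comp)

where C is the total cost of managing the cohort (screening plus
stage-wise treatment) and E the cohort QALYs.  The (ΔE, ΔC) point falls
in one of four plane quadrants: SE (cheaper and more effective — the
new strategy dominates), NW (dearer and less effective — dominated),
NE/SW — a trade-off priced by the willingness-to-pay threshold.  A bare
negative ICER is ambiguous (SE and NW both produce one), so results
always carry the quadrant and dominance label alongside the ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .costing import ARMS
from .errors import InvalidInputError
from .outcomes import STAGES

QUADRANTS = ("NE", "SE", "SW", "NW")

DOMINANT = "dominant"
DOMINATED = "dominated"
TRADE_OFF = "trade_off"

HIGHLY_COST_EFFECTIVE = "highly_cost_effective"
COST_EFFECTIVE = "cost_effective"
NOT_COST_EFFECTIVE = "not_cost_effective"
NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class ManagementCost:
    """Cohort-level cost of managing one arm: stage-wise treatment costs
    times stage counts, plus the cohort screening cost."""

    arm: str
    treatment_cost_per_stage: Mapping[str, float]
    stage_counts: Mapping[str, int]
    screening_cost_per_cohort: float

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise InvalidInputError(f"unknown arm {self.arm!r}")
        if self.screening_cost_per_cohort < 0:
            raise InvalidInputError("screening cost must be non-negative")
        for stage, n in self.stage_counts.items():
            if stage not in STAGES:
                raise InvalidInputError(f"unknown stage {stage!r}")
            if n < 0:
                raise InvalidInputError("stage counts must be non-negative")

    @property
    def total(self) -> float:
        return total_management_cost(self)


@dataclass(frozen=True)
class CEAResult:
    """ICER core: cohort-level deltas, the ratio, and its plane/threshold
    interpretation."""

    delta_cost: float
    delta_effect: float
    icer: float | None
    quadrant: str
    dominance: str
    threshold_class: str = NOT_APPLICABLE


def cost_per_effect(provider_cost: float, effect: float) -> float:
    """Cost per unit of effect (per LY or per QALY); plain division."""
    if effect <= 0:
        raise InvalidInputError("effect must be positive")
    return provider_cost / effect


def cost_ratios(
    cost_per_ly_new: float,
    cost_per_ly_comp: float,
    cost_per_qaly_new: float,
    cost_per_qaly_comp: float,
) -> dict[str, float]:
    """New-over-comparator cost ratios per LY and per QALY."""
    if cost_per_ly_comp <= 0 or cost_per_qaly_comp <= 0:
        raise InvalidInputError("comparator cost-per-effect must be positive")
    return {
        "ratio_ly": cost_per_ly_new / cost_per_ly_comp,
        "ratio_qaly": cost_per_qaly_new / cost_per_qaly_comp,
    }


def total_management_cost(mc: ManagementCost) -> float:
    """Σ_k treatment_cost_k · n_k + cohort screening cost."""
    total = mc.screening_cost_per_cohort
    for stage, n in mc.stage_counts.items():
        if n > 0:
            if stage not in mc.treatment_cost_per_stage:
                raise InvalidInputError(
                    f"stage {stage!r} has patients but no treatment cost"
                )
            total += mc.treatment_cost_per_stage[stage] * n
    return total


def classify_quadrant(delta_cost: float, delta_effect: float) -> tuple[str, str]:
    """Plane quadrant and dominance label for a (ΔC, ΔE) sign pattern.

    Axis cases attach to the non-dominance interpretation: ΔE = 0 splits
    by cost sign (N/S boundary treated as NE for ΔC > 0, SW for ΔC < 0,
    by convention NE for the origin); ΔC = 0 splits by effect sign.
    Strict dominance requires strict inequalities in both coordinates.
    """
    if delta_cost < 0 and delta_effect > 0:
        return "SE", DOMINANT
    if delta_cost > 0 and delta_effect < 0:
        return "NW", DOMINATED
    if delta_effect >= 0:
        return ("NE" if delta_cost >= 0 else "SE"), TRADE_OFF
    return ("SW" if delta_cost <= 0 else "NW"), TRADE_OFF


def icer(
    cost_new: float,
    cost_comp: float,
    effect_new: float,
    effect_comp: float,
    gdp_per_capita: float | None = None,
) -> CEAResult:
    """ICER of the new strategy versus the comparator, with quadrant,
    dominance, and (when a GDP per capita is supplied) threshold class.

    ΔE = 0 yields an undefined ratio (None) with the quadrant set by the
    cost sign alone.
    """
    delta_cost = cost_new - cost_comp
    delta_effect = effect_new - effect_comp
    quadrant, dominance = classify_quadrant(delta_cost, delta_effect)
    ratio = delta_cost / delta_effect if delta_effect != 0 else None
    threshold = (
        classify_threshold(ratio, dominance, gdp_per_capita)
        if gdp_per_capita is not None
        else NOT_APPLICABLE
    )
    return CEAResult(
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=ratio,
        quadrant=quadrant,
        dominance=dominance,
        threshold_class=threshold,
    )


def classify_threshold(
    icer_value: float | None, dominance: str, gdp_per_capita: float
) -> str:
    """Willingness-to-pay classification in GDP-per-capita multiples.

    A dominant strategy is highly cost-effective regardless of the
    ratio; a dominated one is never cost-effective.  Otherwise the
    ICER/GDP ratio classifies as: < 1 highly cost-effective, 1–3 cost-
    effective, > 3 not cost-effective (the conventional WHO-style bands;
    the 1–2 multiple range is folded into cost-effective).
    """
    if gdp_per_capita <= 0:
        raise InvalidInputError("GDP per capita must be positive")
    if dominance == DOMINANT:
        return HIGHLY_COST_EFFECTIVE
    if dominance == DOMINATED:
        return NOT_COST_EFFECTIVE
    if icer_value is None or math.isnan(icer_value):
        return NOT_APPLICABLE
    multiples = icer_value / gdp_per_capita
    if multiples < 1:
        return HIGHLY_COST_EFFECTIVE
    if multiples <= 3:
        return COST_EFFECTIVE
    return NOT_COST_EFFECTIVE
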