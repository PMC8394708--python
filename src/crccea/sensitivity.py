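"""Deterministic one-way sensitivity analysis over discount rates.

Two discounting rules are offered:

* ``paper_multiplicative`` — a one-shot cost-reduction: value × (1 − r).
  This is the rule the source study applies to every cost, LY and QALY
  cell of its sensitivity table (its published cells all equal the base
  case times 0.97 or 0.95), and is the fixture default.
* ``exponential`` — conventional time discounting value / (1 + r)^t,
  with a default horizon of one year (the costing period).

Both leave the base case untouched at r = 0.  The one-shot rule is
linear, so the discounted between-arm cost difference equals the
difference of the discounted costs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import InvalidInputError

PAPER_MULTIPLICATIVE = "paper_multiplicative"
EXPONENTIAL = "exponential"
METHODS = (PAPER_MULTIPLICATIVE, EXPONENTIAL)


@dataclass(frozen=True)
class DiscountScenario:
    """One scenario: a label, a rate in [0, 1) and a discounting rule."""

    label: str
    rate: float
    method: str = PAPER_MULTIPLICATIVE

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate < 1.0):
            raise InvalidInputError(f"rate {self.rate} outside [0, 1)")
        if self.method not in METHODS:
            raise InvalidInputError(f"unknown discount method {self.method!r}")


@dataclass(frozen=True)
class ScenarioResult:
    """Discounted per-arm costs/LYs/QALYs plus the cost difference."""

    scenario: DiscountScenario
    per_arm: Mapping[str, Mapping[str, float]]
    cost_difference: float


def apply_discount(
    value: float, rate: float, method: str = PAPER_MULTIPLICATIVE, horizon: float = 1.0
) -> float:
    """Discount a value: multiplicative one-shot (1 − r) or exponential
    1/(1 + r)^horizon."""
    if not (0.0 <= rate < 1.0):
        raise InvalidInputError(f"rate {rate} outside [0, 1)")
    if method == PAPER_MULTIPLICATIVE:
        return value * (1.0 - rate)
    if method == EXPONENTIAL:
        return value / (1.0 + rate) ** horizon
    raise InvalidInputError(f"unknown discount method {method!r}")


def run_scenarios(
    base: Mapping[str, Mapping[str, float]],
    rates: Sequence[float],
    method: str = PAPER_MULTIPLICATIVE,
    base_cost_difference: float | None = None,
    horizon: float = 1.0,
) -> list[ScenarioResult]:
    """Discount every base-case cell per scenario.

    `base` maps arm → {"provider_cost": ..., "ly": ..., "qaly": ...}.
    The base case (rate 0) always leads the result list.  The cost
    difference row discounts `base_cost_difference` when supplied (a
    source table may carry a difference at higher precision than its
    printed arm costs); otherwise the difference of the two arms'
    discounted costs — identical under the multiplicative rule whenever
    the difference is consistent with the costs.
    """
    if len(base) != 2:
        raise InvalidInputError("base values must cover exactly two arms")
    arms = list(base)
    for arm, cells in base.items():
        missing = {"provider_cost", "ly", "qaly"} - set(cells)
        if missing:
            raise InvalidInputError(f"arm {arm!r} missing base values {sorted(missing)}")

    if base_cost_difference is None:
        base_cost_difference = (
            base[arms[1]]["provider_cost"] - base[arms[0]]["provider_cost"]
        )

    scenarios = [DiscountScenario("base_case", 0.0, method)] + [
        DiscountScenario(f"rate_{r:g}", r, method) for r in rates
    ]
    results = []
    for sc in scenarios:
        per_arm = {
            arm: {
                key: apply_discount(val, sc.rate, sc.method, horizon)
                for key, val in cells.items()
            }
            for arm, cells in base.items()
        }
        diff = apply_discount(base_cost_difference, sc.rate, sc.method, horizon)
        results.append(ScenarioResult(scenario=sc, per_arm=per_arm, cost_difference=diff))
    return results
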