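"""Provider costing for the two screening arms.

Annual per-patient provider costs are built from itemized components
(building, equipment, human resource, administration, utilities,
maintenance, medication, consumables, laboratory), each obtained either
by top-down costing (aggregate expenditure divided by patient volume,
scaled by mean visits) or activity-based costing (summing the costs of
the activities the service directly consumes).  Components carry a
capital/recurrent category and an optional standard error.

All arithmetic is kept at full floating precision; rounding to two
decimals happens only when a table is rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, InvalidInputError

ARM_IFOBT = "iFOBT"
ARM_GT = "genetic_testing"
ARMS = (ARM_IFOBT, ARM_GT)

CATEGORIES = ("capital", "recurrent")
METHODS = ("top_down", "activity_based")

# two-sided 95% normal quantile, used for difference intervals
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class CostComponent:
    """One itemized cost line of an arm's annual per-patient cost."""

    name: str
    category: str
    method: str
    amount: float
    se: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidInputError(f"unknown category {self.category!r}")
        if self.method not in METHODS:
            raise InvalidInputError(f"unknown costing method {self.method!r}")
        if self.amount < 0:
            raise InvalidInputError(f"negative amount for {self.name!r}")
        if self.se is not None and self.se < 0:
            raise InvalidInputError(f"negative SE for {self.name!r}")


@dataclass(frozen=True)
class CostProfile:
    """An arm's annual per-patient provider cost, itemized by component."""

    arm: str
    components: tuple[CostComponent, ...]

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise InvalidInputError(f"unknown arm {self.arm!r}")
        if not self.components:
            raise InvalidInputError("cost profile needs at least one component")

    @property
    def total(self) -> float:
        return float(sum(c.amount for c in self.components))

    def component(self, name: str) -> CostComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise InvalidInputError(f"no component named {name!r}")


@dataclass(frozen=True)
class CurrencySpec:
    """Exchange-rate spec: `rate` units of `from_currency` per unit of
    `to_currency` (e.g. 4.14 RM per USD for price year 2019)."""

    from_currency: str
    to_currency: str
    rate: float
    price_year: int = 2019

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise InvalidInputError("exchange rate must be positive")


@dataclass(frozen=True)
class CostDifference:
    """Componentwise and total mean differences between two profiles."""

    per_component: Mapping[str, float]
    total: float
    total_ci: tuple[float, float] | None = None
    per_component_ci: Mapping[str, tuple[float, float]] = field(default_factory=dict)


def top_down_unit_cost(
    total_expenditure: float, n_patients: int, mean_visits: float = 1.0
) -> float:
    """Top-down unit cost: aggregate expenditure over patient volume,
    scaled by the average number of visits per patient."""
    if n_patients <= 0:
        raise InvalidInputError("n_patients must be positive")
    if total_expenditure < 0:
        raise InvalidInputError("expenditure must be non-negative")
    if mean_visits <= 0:
        raise InvalidInputError("mean_visits must be positive")
    return total_expenditure / n_patients * mean_visits


def activity_based_unit_cost(activity_costs: Iterable[float]) -> float:
    """Activity-based unit cost: sum of the per-activity costs."""
    costs = list(activity_costs)
    if any(c < 0 for c in costs):
        raise InvalidInputError("activity costs must be non-negative")
    return float(sum(costs))


def convert_currency(amount: float, spec: CurrencySpec, direction: str = "forward") -> float:
    """Convert `amount` along the spec: forward = from→to (divide by rate,
    e.g. RM→USD), inverse = to→from (multiply)."""
    if amount < 0:
        raise InvalidInputError("amount must be non-negative")
    if direction == "forward":
        return amount / spec.rate
    if direction == "inverse":
        return amount * spec.rate
    raise ConfigurationError(f"unknown conversion direction {direction!r}")


def adjust_to_price_year(amount: float, cpi_index: float = 1.0) -> float:
    """Multiplicative consumer-price-index adjustment to the analysis
    price year.  The index is user-supplied; the default 1.0 leaves the
    amount unchanged."""
    if cpi_index <= 0:
        raise InvalidInputError("CPI index must be positive")
    return amount * cpi_index


def build_cost_profile(components: Sequence[CostComponent], arm: str) -> CostProfile:
    """Assemble an arm's cost profile; the total is the full-precision sum."""
    if not components:
        raise InvalidInputError("component list is empty")
    return CostProfile(arm=arm, components=tuple(components))


def cost_difference(profile_a: CostProfile, profile_b: CostProfile) -> CostDifference:
    """Componentwise and total mean differences a − b.

    When both components carry SEs, a normal-approximation 95% interval
    diff ± 1.96·sqrt(se_a² + se_b²) is attached.  Published intervals
    from the source tables are carried separately by the fixture, never
    recomputed here.
    """
    names_a = [c.name for c in profile_a.components]
    names_b = [c.name for c in profile_b.components]
    if sorted(names_a) != sorted(names_b):
        raise InvalidInputError("profiles have mismatched component sets")

    per_component: dict[str, float] = {}
    per_component_ci: dict[str, tuple[float, float]] = {}
    var_total = 0.0
    have_all_ses = True
    for name in names_a:
        ca, cb = profile_a.component(name), profile_b.component(name)
        diff = ca.amount - cb.amount
        per_component[name] = diff
        if ca.se is not None and cb.se is not None:
            se = math.hypot(ca.se, cb.se)
            per_component_ci[name] = (diff - _Z95 * se, diff + _Z95 * se)
            var_total += se * se
        else:
            have_all_ses = False

    total = profile_a.total - profile_b.total
    total_ci = None
    if have_all_ses:
        se_tot = math.sqrt(var_total)
        total_ci = (total - _Z95 * se_tot, total + _Z95 * se_tot)
    return CostDifference(
        per_component=per_component,
        total=total,
        total_ci=total_ci,
        per_component_ci=per_component_ci,
    )
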