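"""EQ-5D-5L health-related quality-of-life outcomes.

An EQ-5D-5L response is a five-dimension profile (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression), each scored at a
level 1 (no problems) to 5 (extreme problems), plus a 0–100 visual
analogue scale (VAS) self-rating.  A country value set maps the profile
to a utility index anchored at 1 for full health (1,1,1,1,1); levels
above 1 subtract value-set decrements and the index may go negative.

The value set is pluggable: a documented linear toy set (0.05 per level
step per dimension) supports testing and synthetic-cohort work, and
`load_value_set` reads externally supplied coefficient tables.  No
national tariff is bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .costing import ARMS
from .errors import InvalidInputError

DIMENSIONS = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

STAGES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class EQ5DProfile:
    """One EQ-5D-5L descriptive response; levels 1 (best) to 5 (worst)."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if not (isinstance(level, (int, np.integer)) and 1 <= level <= 5):
                raise InvalidInputError(f"{dim} level {level!r} outside 1..5")

    def level(self, dimension: str) -> int:
        if dimension not in DIMENSIONS:
            raise InvalidInputError(f"unknown dimension {dimension!r}")
        return int(getattr(self, dimension))

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return tuple(getattr(self, d) for d in DIMENSIONS)  # type: ignore[return-value]


@dataclass(frozen=True)
class ValueSet:
    """Maps profiles to utility indexes via per-dimension, per-level
    decrements from the full-health anchor.

    `decrements[dim][level]` is subtracted from 1.0 for a response at
    `level` (2..5) in `dim`; level 1 contributes nothing, so (1,1,1,1,1)
    always maps to exactly 1.
    """

    name: str
    decrements: Mapping[str, Mapping[int, float]]

    def utility(self, profile: EQ5DProfile) -> float:
        total = 1.0
        for dim in DIMENSIONS:
            level = profile.level(dim)
            if level > 1:
                total -= self.decrements[dim][level]
        return total


def linear_toy_value_set(step: float = 0.05) -> ValueSet:
    """Linear toy tariff: each level above 1 subtracts `step` per step,
    so utility = 1 − Σ step·(level−1).  Worst state (5,5,5,5,5) scores
    1 − 20·step (0.0 at the default step)."""
    decs = {dim: {lvl: step * (lvl - 1) for lvl in range(2, 6)} for dim in DIMENSIONS}
    return ValueSet(name=f"linear_toy_{step}", decrements=decs)


def load_value_set(path, name: str = "custom") -> ValueSet:
    """Read a coefficient table (columns: dimension, level, decrement)
    into a ValueSet.  Levels 2–5 must be covered for every dimension."""
    df = pd.read_csv(path)
    missing = {"dimension", "level", "decrement"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"value-set file missing columns {sorted(missing)}")
    decs: dict[str, dict[int, float]] = {d: {} for d in DIMENSIONS}
    for row in df.itertuples(index=False):
        if row.dimension not in DIMENSIONS:
            raise InvalidInputError(f"unknown dimension {row.dimension!r}")
        decs[row.dimension][int(row.level)] = float(row.decrement)
    for dim, table in decs.items():
        if set(table) != {2, 3, 4, 5}:
            raise InvalidInputError(f"dimension {dim!r} must define levels 2..5")
    return ValueSet(name=name, decrements=decs)


@dataclass
class PatientRecord:
    """One (possibly synthetic) patient: arm, cancer stage, EQ-5D-5L
    profile, VAS and utility."""

    id: str
    arm: str
    stage: str
    profile: EQ5DProfile
    vas: float
    utility: float
    demographics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise InvalidInputError(f"unknown arm {self.arm!r}")
        if self.stage not in STAGES:
            raise InvalidInputError(f"unknown stage {self.stage!r}")
        if not (0.0 <= self.vas <= 100.0):
            raise InvalidInputError(f"VAS {self.vas} outside [0, 100]")
        if self.utility > 1.0:
            raise InvalidInputError(f"utility {self.utility} above 1")


@dataclass(frozen=True)
class OutcomeSummary:
    """Per-group descriptive summary mirroring a published HRQoL table."""

    group: str
    n: int
    problem_proportions: Mapping[str, float]
    utility_mean: float
    utility_sd: float
    utility_median: float
    vas_mean: float
    vas_sd: float
    vas_median: float


def utility_index(profile: EQ5DProfile, value_set: ValueSet) -> float:
    """Utility index of a profile under the supplied value set."""
    return value_set.utility(profile)


def has_problem(profile: EQ5DProfile, dimension: str) -> bool:
    """A dimension counts as a reported problem at any level above 1."""
    return profile.level(dimension) > 1


def summarize_outcomes(
    cohort: Iterable[PatientRecord], group_by: str = "all"
) -> OutcomeSummary:
    """Problem proportions per dimension plus utility/VAS means, SDs
    (sample SD, ddof=1) and medians, for one arm or the whole cohort."""
    records = [p for p in cohort if group_by == "all" or p.arm == group_by]
    if not records:
        raise InvalidInputError(f"no patients in group {group_by!r}")
    n = len(records)
    props = {
        dim: sum(has_problem(p.profile, dim) for p in records) / n for dim in DIMENSIONS
    }
    utils = np.array([p.utility for p in records], dtype=float)
    vas = np.array([p.vas for p in records], dtype=float)
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return OutcomeSummary(
        group=group_by,
        n=n,
        problem_proportions=props,
        utility_mean=float(utils.mean()),
        utility_sd=sd(utils),
        utility_median=float(np.median(utils)),
        vas_mean=float(vas.mean()),
        vas_sd=sd(vas),
        vas_median=float(np.median(vas)),
    )


def cohort_from_csv(path, value_set: ValueSet | None = None) -> list[PatientRecord]:
    """Read a patient-level CSV (id, arm, stage, mo, sc, ua, pd, ad, vas
    [, utility]).  Missing utilities are scored with `value_set`
    (defaults to the linear toy set)."""
    df = pd.read_csv(path)
    vs = value_set or linear_toy_value_set()
    records = []
    for row in df.itertuples(index=False):
        profile = EQ5DProfile(
            int(row.mo), int(row.sc), int(row.ua), int(row.pd), int(row.ad)
        )
        utility = float(row.utility) if hasattr(row, "utility") else vs.utility(profile)
        records.append(
            PatientRecord(
                id=str(row.id),
                arm=str(row.arm),
                stage=str(row.stage),
                profile=profile,
                vas=float(row.vas),
                utility=utility,
            )
        )
    return records
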