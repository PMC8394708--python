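"""Synthetic patient-level cohorts with the study's aggregate structure.

The published analysis works on aggregates (arm×stage counts, stage
utility means, cost components); this module generates patient-level
cohorts consistent with those aggregates so every pipeline stage can be
exercised end to end.  Per arm, stage membership follows the published
stage distribution (iFOBT 6/17/54/23, genetic testing 10/60/25/5 per
100 across stages I–IV), utilities are truncated-normal draws around
the arm×stage means (sd defaulting to the overall published utility SD
0.273, truncated above at 1), VAS scores are normal draws clipped to
[0, 100], and each patient gets an EQ-5D-5L profile whose linear-toy
index approximates the drawn utility.

Profiles are plumbing for the outcomes module and carry no clinical
claim; the generator emulates marginal structure only (no demographic
covariate effects on utility, no within-patient VAS–utility
correlation beyond their shared stage).

Deterministic allocation mode assigns exact expected stage counts
(largest-remainder apportionment); with ``utility_sd = 0`` the cohort
reproduces the study aggregates exactly, which the test-suite uses for
parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .costing import ARM_GT, ARM_IFOBT
from .effectiveness import StageRow, StageTable
from .errors import InvalidInputError
from .outcomes import DIMENSIONS, STAGES, EQ5DProfile, PatientRecord, linear_toy_value_set

# published arm×stage structure: stage fractions and utility means
DEFAULT_STAGE_PROBS: dict[str, tuple[float, ...]] = {
    ARM_IFOBT: (0.06, 0.17, 0.54, 0.23),
    ARM_GT: (0.10, 0.60, 0.25, 0.05),
}
DEFAULT_UTILITY_MEANS: dict[str, dict[str, float]] = {
    ARM_IFOBT: {"I": 0.87, "II": 0.74, "III": 0.72, "IV": 0.11},
    ARM_GT: {"I": 0.85, "II": 0.82, "III": 0.77, "IV": 0.75},
}
DEFAULT_SURVIVAL_MEANS: dict[str, float] = {"I": 6.71, "II": 6.51, "III": 5.65, "IV": 2.84}

# overall published utility SD and VAS moments
DEFAULT_UTILITY_SD = 0.273
DEFAULT_VAS_MEAN = 73.58
DEFAULT_VAS_SD = 18.47


@dataclass(frozen=True)
class CohortParams:
    """Generator parameters; the defaults are the study's conditions."""

    n_per_arm: int = 100
    stage_probs: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_PROBS)
    )
    utility_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {a: dict(m) for a, m in DEFAULT_UTILITY_MEANS.items()}
    )
    utility_sd: float = DEFAULT_UTILITY_SD
    vas_mean: float = DEFAULT_VAS_MEAN
    vas_sd: float = DEFAULT_VAS_SD
    seed: int = 0
    deterministic_allocation: bool = False

    def __post_init__(self) -> None:
        if self.n_per_arm <= 0:
            raise InvalidInputError("n_per_arm must be positive")
        if self.utility_sd < 0 or self.vas_sd < 0:
            raise InvalidInputError("standard deviations must be non-negative")
        for arm, probs in self.stage_probs.items():
            p = np.asarray(probs, dtype=float)
            if len(p) != len(STAGES) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise InvalidInputError(
                    f"stage probabilities for {arm!r} must be a 4-vector summing to 1"
                )


def _largest_remainder_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Exact expected counts by largest-remainder apportionment."""
    raw = probs * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def _profile_for_utility(utility: float, rng: np.random.Generator) -> EQ5DProfile:
    """EQ-5D-5L profile whose linear-toy index (step 0.05) approximates
    `utility`: the implied decrement is spread over randomly ordered
    dimensions, each absorbing at most four level steps."""
    deficit = int(np.clip(round((1.0 - utility) / 0.05), 0, 20))
    levels = {dim: 1 for dim in DIMENSIONS}
    for dim in rng.permutation(DIMENSIONS):
        take = min(4, deficit)
        levels[str(dim)] += take
        deficit -= take
    return EQ5DProfile(**levels)


def _draw_utility(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return mean
    upper = (1.0 - mean) / sd  # truncate at the full-health ceiling
    return float(stats.truncnorm.rvs(-np.inf, upper, loc=mean, scale=sd, random_state=rng))


def generate_cohort(params: CohortParams) -> list[PatientRecord]:
    """Generate both arms' patients; deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    records: list[PatientRecord] = []
    for arm in (ARM_IFOBT, ARM_GT):
        probs = np.asarray(params.stage_probs[arm], dtype=float)
        if params.deterministic_allocation:
            counts = _largest_remainder_counts(probs, params.n_per_arm)
        else:
            counts = rng.multinomial(params.n_per_arm, probs)
        idx = 0
        for stage, count in zip(STAGES, counts):
            mean_u = params.utility_means[arm][stage]
            for _ in range(int(count)):
                utility = _draw_utility(mean_u, params.utility_sd, rng)
                vas = float(np.clip(rng.normal(params.vas_mean, params.vas_sd), 0, 100))
                records.append(
                    PatientRecord(
                        id=f"{arm}-{idx:04d}",
                        arm=arm,
                        stage=stage,
                        profile=_profile_for_utility(utility, rng),
                        vas=vas,
                        utility=utility,
                    )
                )
                idx += 1
    return records


def cohort_to_stage_table(
    cohort: Sequence[PatientRecord],
    survival_means: Mapping[str, float],
    arm: str,
    treatment_costs: Mapping[str, float] | None = None,
) -> StageTable:
    """Aggregate one arm of a patient-level cohort into the stage-table
    shape the effectiveness stage consumes: n_k from stage counts, u_k
    as the mean observed utility, s_k passed through."""
    rows: dict[str, StageRow] = {}
    for stage in STAGES:
        patients = [p for p in cohort if p.arm == arm and p.stage == stage]
        if patients and stage not in survival_means:
            raise InvalidInputError(f"stage {stage!r} has patients but no survival mean")
        rows[stage] = StageRow(
            survival_mean=float(survival_means.get(stage, 0.0)),
            n=len(patients),
            utility_mean=float(np.mean([p.utility for p in patients]))
            if patients
            else None,
            treatment_cost=treatment_costs.get(stage) if treatment_costs else None,
        )
    return StageTable(arm=arm, rows=rows)


def cohort_to_frame(cohort: Sequence[PatientRecord]):
    """Patient-level DataFrame in the outcomes module's CSV schema."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [p.id for p in cohort],
            "arm": [p.arm for p in cohort],
            "stage": [p.stage for p in cohort],
            "mo": [p.profile.mobility for p in cohort],
            "sc": [p.profile.self_care for p in cohort],
            "ua": [p.profile.usual_activities for p in cohort],
            "pd": [p.profile.pain_discomfort for p in cohort],
            "ad": [p.profile.anxiety_depression for p in cohort],
            "vas": [p.vas for p in cohort],
            "utility": [p.utility for p in cohort],
        }
    )


__all__ = [
    "CohortParams",
    "generate_cohort",
    "cohort_to_stage_table",
    "cohort_to_frame",
    "DEFAULT_STAGE_PROBS",
    "DEFAULT_UTILITY_MEANS",
    "DEFAULT_SURVIVAL_MEANS",
    "linear_toy_value_set",
]
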