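"""Stage-wise life-years and QALYs per arm.

For each cancer stage k with mean survival s_k (years), patient count
n_k and mean utility u_k, the arm accrues LY_k = s_k·n_k life-years and
QALY_k = s_k·n_k·u_k quality-adjusted life-years.  Totals are sums over
stages; per-patient values divide by the arm cohort size Σ n_k.  Stage
survival means are exogenous inputs (here restricted 10-year means from
a national cancer-survival report); no survival modelling happens here.

Totals are accumulated at full precision and rounded only for display:
summing per-stage values that were themselves rounded to 2 dp can land
one cent off the correct total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .costing import ARMS
from .errors import InvalidInputError
from .outcomes import STAGES


@dataclass(frozen=True)
class StageRow:
    """One stage's inputs: survival mean (years), count, utility mean."""

    survival_mean: float
    n: int
    utility_mean: float | None = None
    treatment_cost: float | None = None

    def __post_init__(self) -> None:
        if self.survival_mean < 0:
            raise InvalidInputError("survival mean must be non-negative")
        if self.n < 0:
            raise InvalidInputError("stage count must be non-negative")
        if self.utility_mean is not None and not (-1.0 <= self.utility_mean <= 1.0):
            raise InvalidInputError("utility mean outside [-1, 1]")


@dataclass(frozen=True)
class StageTable:
    """Per-stage survival/count/utility inputs for one arm; all four
    stages I–IV present exactly once."""

    arm: str
    rows: Mapping[str, StageRow]

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise InvalidInputError(f"unknown arm {self.arm!r}")
        if set(self.rows) != set(STAGES):
            raise InvalidInputError(f"stage table must cover stages {STAGES}")

    @property
    def cohort_size(self) -> int:
        return sum(r.n for r in self.rows.values())

    @classmethod
    def from_frame(cls, df: pd.DataFrame, arm: str) -> "StageTable":
        sub = df[df["arm"] == arm]
        rows = {}
        for rec in sub.itertuples(index=False):
            rows[str(rec.stage)] = StageRow(
                survival_mean=float(rec.survival_mean),
                n=int(rec.n),
                utility_mean=float(rec.utility_mean)
                if "utility_mean" in sub.columns and pd.notna(rec.utility_mean)
                else None,
                treatment_cost=float(rec.treatment_cost)
                if "treatment_cost" in sub.columns and pd.notna(rec.treatment_cost)
                else None,
            )
        return cls(arm=arm, rows=rows)


@dataclass(frozen=True)
class EffectivenessResult:
    """Total and per-patient LYs/QALYs for one arm with the per-stage
    breakdown (ly_k = s_k·n_k, qaly_k = ly_k·u_k)."""

    arm: str
    per_stage_ly: Mapping[str, float]
    per_stage_qaly: Mapping[str, float] | None
    total_ly: float
    total_qaly: float | None
    per_patient_ly: float
    per_patient_qaly: float | None


def stage_lys(table: StageTable) -> EffectivenessResult:
    """Life-years per stage and in total: LY_k = s_k · n_k."""
    if table.cohort_size == 0:
        raise InvalidInputError("cohort size is zero")
    per_stage = {k: r.survival_mean * r.n for k, r in table.rows.items()}
    total = sum(per_stage.values())
    return EffectivenessResult(
        arm=table.arm,
        per_stage_ly=per_stage,
        per_stage_qaly=None,
        total_ly=total,
        total_qaly=None,
        per_patient_ly=total / table.cohort_size,
        per_patient_qaly=None,
    )


def stage_qalys(table: StageTable) -> EffectivenessResult:
    """QALYs per stage and in total: QALY_k = s_k · n_k · u_k, computed
    at full precision (no per-cell rounding)."""
    if table.cohort_size == 0:
        raise InvalidInputError("cohort size is zero")
    per_stage_ly = {k: r.survival_mean * r.n for k, r in table.rows.items()}
    per_stage_qaly: dict[str, float] = {}
    for k, r in table.rows.items():
        if r.n > 0 and r.utility_mean is None:
            raise InvalidInputError(f"stage {k} has patients but no utility mean")
        per_stage_qaly[k] = per_stage_ly[k] * (r.utility_mean or 0.0)
    total_ly = sum(per_stage_ly.values())
    total_qaly = sum(per_stage_qaly.values())
    size = table.cohort_size
    return EffectivenessResult(
        arm=table.arm,
        per_stage_ly=per_stage_ly,
        per_stage_qaly=per_stage_qaly,
        total_ly=total_ly,
        total_qaly=total_qaly,
        per_patient_ly=total_ly / size,
        per_patient_qaly=total_qaly / size,
    )


def gains(
    result_new: EffectivenessResult, result_comparator: EffectivenessResult
) -> dict[str, float]:
    """Per-patient LY and QALY gains of the new arm over the comparator."""
    out = {"ly_gain": result_new.per_patient_ly - result_comparator.per_patient_ly}
    if (
        result_new.per_patient_qaly is not None
        and result_comparator.per_patient_qaly is not None
    ):
        out["qaly_gain"] = (
            result_new.per_patient_qaly - result_comparator.per_patient_qaly
        )
    return out
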