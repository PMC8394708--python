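"""Packaged study tables: the canonical aggregate inputs of the analysis.

The study published every quantitative input it used — per-arm cost
components with standard errors, stage-specific survival means (10-year
restricted means from a national cancer-survival report), arm×stage
patient counts and utility means, stage-wise treatment costs, cohort
screening costs, as-published HRQoL summaries, and the expected
sensitivity-table cells.  These ship as small CSVs inside the package
so the full pipeline runs with no downloads; a JSON manifest of SHA-256
checksums guards against corrupted package data.

The HRQoL summary table is stored strictly as published (its respondent
denominators are not consistent with the 200-patient cohort and cannot
be reconstructed at the patient level); it is a pass-through display
table, never an input to the LY/QALY chain, which uses the arm×stage
utility means.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

from .cea import ManagementCost
from .costing import ARM_GT, ARM_IFOBT, CostComponent, CostProfile
from .effectiveness import StageTable
from .errors import IntegrityError

_DATA_PACKAGE = "crccea.data"

FIXTURE_FILES = (
    "cost_components.csv",
    "published_cost_differences.csv",
    "stage_tables.csv",
    "screening_costs.csv",
    "outcome_summary.csv",
    "scenario_expectations.csv",
)


@dataclass(frozen=True)
class PaperFixture:
    """All packaged aggregates, typed and ready for the pipeline."""

    cost_profiles: Mapping[str, CostProfile]
    published_cost_differences: pd.DataFrame
    stage_tables: Mapping[str, StageTable]
    management_costs: Mapping[str, ManagementCost]
    screening_costs: Mapping[str, float]
    outcome_summaries: pd.DataFrame
    scenario_expectations: pd.DataFrame

    @property
    def published_total_cost_difference(self) -> float:
        row = self.published_cost_differences
        return float(row.loc[row["name"] == "total", "mean"].iloc[0])


def _data_path(name: str):
    return resources.files(_DATA_PACKAGE).joinpath(name)


def _verify_checksums() -> None:
    manifest = json.loads(_data_path("manifest.json").read_text())
    for name, expected in manifest["sha256"].items():
        digest = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
        if digest != expected:
            raise IntegrityError(f"packaged data file {name!r} failed its checksum")


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        return pd.read_csv(path)


def load_paper_fixture(verify: bool = True) -> PaperFixture:
    """Load (and by default checksum-verify) the packaged study tables."""
    if verify:
        _verify_checksums()

    comp_df = _read("cost_components.csv")
    profiles: dict[str, CostProfile] = {}
    for arm in (ARM_IFOBT, ARM_GT):
        sub = comp_df[comp_df["arm"] == arm]
        components = tuple(
            CostComponent(
                name=str(r.name),
                category=str(r.category),
                method=str(r.method),
                amount=float(r.amount),
                se=float(r.se),
            )
            for r in sub.itertuples(index=False)
        )
        profiles[arm] = CostProfile(arm=arm, components=components)

    stage_df = _read("stage_tables.csv")
    stage_tables = {
        arm: StageTable.from_frame(stage_df, arm) for arm in (ARM_IFOBT, ARM_GT)
    }

    screening_df = _read("screening_costs.csv")
    screening = {
        str(r.arm): float(r.screening_cost_per_cohort)
        for r in screening_df.itertuples(index=False)
    }

    management = {}
    for arm, table in stage_tables.items():
        management[arm] = ManagementCost(
            arm=arm,
            treatment_cost_per_stage={
                k: row.treatment_cost
                for k, row in table.rows.items()
                if row.treatment_cost is not None
            },
            stage_counts={k: row.n for k, row in table.rows.items()},
            screening_cost_per_cohort=screening[arm],
        )

    return PaperFixture(
        cost_profiles=profiles,
        published_cost_differences=_read("published_cost_differences.csv"),
        stage_tables=stage_tables,
        management_costs=management,
        screening_costs=screening,
        outcome_summaries=_read("outcome_summary.csv"),
        scenario_expectations=_read("scenario_expectations.csv"),
    )
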