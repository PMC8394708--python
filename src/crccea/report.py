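"""Pipeline orchestration and table rendering.

``run_pipeline`` executes the full chain — costing → effectiveness →
CEA engine → discount sensitivity — from a run configuration, returning
a results bundle and optionally writing CSV tables, a JSON manifest
(headline numbers at full precision plus 2-dp display values), a
CE-plane point list and a run log.

Reporting conventions, matching the source tables:

* Display rounding is round-half-even at 2 dp; internal arithmetic is
  never rounded.
* Cost-per-LY/QALY ratios divide the provider cost by the 2-dp-rounded
  per-patient effect, because that is how the published summary table
  is computed; the full-precision ratios are also carried in the
  manifest under ``*_full_precision``.
* The sensitivity grid likewise starts from the 2-dp per-patient base
  cells, and its cost-difference row discounts the as-published
  base-case difference.
* The ICER chain uses cohort-level totals at full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cea, costing, effectiveness, fixtures, outcomes, sensitivity
from .costing import ARM_GT, ARM_IFOBT
from .errors import ConfigurationError, CRCCEAError, InvalidInputError
from .outcomes import STAGES

logger = logging.getLogger("crccea")

LAYOUTS = (
    "cost",
    "effectiveness",
    "cea_summary",
    "qaly_per_100",
    "management_cost",
    "sensitivity",
)


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    With all input paths left at None the packaged study tables are
    used; `cohort_csv` optionally adds a patient-level HRQoL summary.
    """

    cost_components_csv: str | None = None
    stage_tables_csv: str | None = None
    screening_costs_csv: str | None = None
    cohort_csv: str | None = None
    gdp_per_capita: float | None = None
    discount_rates: tuple[float, ...] = (0.03, 0.05)
    discount_method: str = sensitivity.PAPER_MULTIPLICATIVE
    output_dir: str | None = None
    seed: int = 0
    new_arm: str = ARM_GT
    comparator_arm: str = ARM_IFOBT


def _round2(x: float) -> float:
    return round(float(x), 2)


def _money(x: float) -> str:
    return f"{x:,.2f}"


def _load_inputs(config: RunConfig):
    fixture = fixtures.load_paper_fixture()
    profiles = dict(fixture.cost_profiles)
    stage_tables = dict(fixture.stage_tables)
    management = dict(fixture.management_costs)
    base_diff = fixture.published_total_cost_difference

    if config.cost_components_csv:
        df = pd.read_csv(config.cost_components_csv)
        profiles = {}
        for arm in (config.comparator_arm, config.new_arm):
            sub = df[df["arm"] == arm]
            comps = [
                costing.CostComponent(
                    name=str(r.name),
                    category=str(r.category),
                    method=str(r.method),
                    amount=float(r.amount),
                    se=float(r.se) if "se" in sub.columns and pd.notna(r.se) else None,
                )
                for r in sub.itertuples(index=False)
            ]
            profiles[arm] = costing.build_cost_profile(comps, arm)
        base_diff = None  # user inputs carry no as-published difference

    if config.stage_tables_csv:
        df = pd.read_csv(config.stage_tables_csv)
        stage_tables = {
            arm: effectiveness.StageTable.from_frame(df, arm)
            for arm in (config.comparator_arm, config.new_arm)
        }
        screening = dict(fixture.screening_costs)
        if config.screening_costs_csv:
            sdf = pd.read_csv(config.screening_costs_csv)
            screening = {
                str(r.arm): float(r.screening_cost_per_cohort)
                for r in sdf.itertuples(index=False)
            }
        management = {
            arm: cea.ManagementCost(
                arm=arm,
                treatment_cost_per_stage={
                    k: row.treatment_cost
                    for k, row in table.rows.items()
                    if row.treatment_cost is not None
                },
                stage_counts={k: row.n for k, row in table.rows.items()},
                screening_cost_per_cohort=screening[arm],
            )
            for arm, table in stage_tables.items()
        }

    return fixture, profiles, stage_tables, management, base_diff


def run_pipeline(config: RunConfig) -> dict:
    """Run the full two-arm cost-effectiveness chain; see module docs."""
    new, comp = config.new_arm, config.comparator_arm

    def stage(name):
        logger.info("stage %s", name)
        return name

    try:
        stage("costing")
        fixture, profiles, stage_tables, management, base_diff = _load_inputs(config)
        diff = costing.cost_difference(profiles[new], profiles[comp])
        cost_results = {
            arm: {
                "total": p.total,
                "components": {c.name: c.amount for c in p.components},
            }
            for arm, p in profiles.items()
        }
        cost_results["difference_total"] = diff.total
    except CRCCEAError as exc:
        raise type(exc)(f"costing stage failed: {exc}") from exc

    try:
        stage("effectiveness")
        eff = {arm: effectiveness.stage_qalys(t) for arm, t in stage_tables.items()}
        gains = effectiveness.gains(eff[new], eff[comp])
    except CRCCEAError as exc:
        raise type(exc)(f"effectiveness stage failed: {exc}") from exc

    try:
        stage("cea")
        # published reporting chain: provider cost over 2-dp per-patient effects
        cpl = {
            arm: cea.cost_per_effect(profiles[arm].total, _round2(e.per_patient_ly))
            for arm, e in eff.items()
        }
        cpq = {
            arm: cea.cost_per_effect(profiles[arm].total, _round2(e.per_patient_qaly))
            for arm, e in eff.items()
        }
        ratios = cea.cost_ratios(cpl[new], cpl[comp], cpq[new], cpq[comp])
        mgmt_totals = {arm: cea.total_management_cost(m) for arm, m in management.items()}
        icer_result = cea.icer(
            mgmt_totals[new],
            mgmt_totals[comp],
            eff[new].total_qaly,
            eff[comp].total_qaly,
            gdp_per_capita=config.gdp_per_capita,
        )
    except CRCCEAError as exc:
        raise type(exc)(f"cea stage failed: {exc}") from exc

    try:
        stage("sensitivity")
        base = {
            arm: {
                "provider_cost": profiles[arm].total,
                "ly": _round2(eff[arm].per_patient_ly),
                "qaly": _round2(eff[arm].per_patient_qaly),
            }
            for arm in (comp, new)
        }
        scenarios = sensitivity.run_scenarios(
            base,
            rates=list(config.discount_rates),
            method=config.discount_method,
            base_cost_difference=base_diff,
        )
        # dominance per scenario: the whole ICER chain rescales by (1 − r)
        scenario_records = []
        for sc in scenarios:
            factor = (
                sc.per_arm[new]["provider_cost"] / base[new]["provider_cost"]
                if base[new]["provider_cost"]
                else 1.0
            )
            sc_icer = cea.icer(
                mgmt_totals[new] * factor,
                mgmt_totals[comp] * factor,
                eff[new].total_qaly * factor,
                eff[comp].total_qaly * factor,
            )
            scenario_records.append(
                {
                    "label": sc.scenario.label,
                    "rate": sc.scenario.rate,
                    "per_arm": {a: dict(v) for a, v in sc.per_arm.items()},
                    "cost_difference": sc.cost_difference,
                    "dominance": sc_icer.dominance,
                    "icer": sc_icer.icer,
                }
            )
    except CRCCEAError as exc:
        raise type(exc)(f"sensitivity stage failed: {exc}") from exc

    outcome_summary = None
    if config.cohort_csv:
        try:
            stage("outcomes")
            cohort = outcomes.cohort_from_csv(config.cohort_csv)
            outcome_summary = {
                group: outcomes.summarize_outcomes(cohort, group)
                for group in ("all", comp, new)
            }
        except CRCCEAError as exc:
            raise type(exc)(f"outcomes stage failed: {exc}") from exc

    results = {
        "config": {
            "new_arm": new,
            "comparator_arm": comp,
            "discount_rates": list(config.discount_rates),
            "discount_method": config.discount_method,
            "gdp_per_capita": config.gdp_per_capita,
            "seed": config.seed,
        },
        "cost": cost_results,
        "effectiveness": {
            arm: {
                "total_ly": e.total_ly,
                "total_qaly": e.total_qaly,
                "per_patient_ly": e.per_patient_ly,
                "per_patient_qaly": e.per_patient_qaly,
                "per_stage_ly": dict(e.per_stage_ly),
                "per_stage_qaly": dict(e.per_stage_qaly),
            }
            for arm, e in eff.items()
        },
        "gains": gains,
        "cea": {
            "cost_per_ly": cpl,
            "cost_per_qaly": cpq,
            "cost_per_ly_full_precision": {
                arm: profiles[arm].total / e.per_patient_ly for arm, e in eff.items()
            },
            "cost_per_qaly_full_precision": {
                arm: profiles[arm].total / e.per_patient_qaly for arm, e in eff.items()
            },
            "ratios": ratios,
            "management_cost": mgmt_totals,
            "delta_cost": icer_result.delta_cost,
            "delta_effect": icer_result.delta_effect,
            "icer": icer_result.icer,
            "quadrant": icer_result.quadrant,
            "dominance": icer_result.dominance,
            "threshold_class": icer_result.threshold_class,
        },
        "sensitivity": scenario_records,
    }
    results["display"] = {
        "icer": _round2(icer_result.icer),
        "delta_cost": _round2(icer_result.delta_cost),
        "delta_effect": _round2(icer_result.delta_effect),
        "cost_per_ly": {a: _round2(v) for a, v in cpl.items()},
        "cost_per_qaly": {a: _round2(v) for a, v in cpq.items()},
        "ratio_ly": _round2(ratios["ratio_ly"]),
        "ratio_qaly": _round2(ratios["ratio_qaly"]),
    }
    if outcome_summary is not None:
        results["outcome_summary"] = {
            g: {
                "n": s.n,
                "problem_proportions": dict(s.problem_proportions),
                "utility_mean": s.utility_mean,
                "utility_sd": s.utility_sd,
                "utility_median": s.utility_median,
                "vas_mean": s.vas_mean,
                "vas_sd": s.vas_sd,
                "vas_median": s.vas_median,
            }
            for g, s in outcome_summary.items()
        }

    if config.output_dir:
        _write_bundle(results, profiles, eff, management, Path(config.output_dir))
    return results


def _write_bundle(results, profiles, eff, management, outdir: Path) -> None:
    """Write all report artifacts; computed-first so a stage failure
    never leaves partial files behind."""
    outdir.mkdir(parents=True, exist_ok=True)
    new = results["config"]["new_arm"]
    comp = results["config"]["comparator_arm"]

    render_table(results, "cost").to_csv(outdir / "cost_profiles.csv", index=False)
    render_table(results, "effectiveness").to_csv(
        outdir / "effectiveness.csv", index=False
    )
    render_table(results, "cea_summary").to_csv(outdir / "cea_summary.csv", index=False)
    render_table(results, "qaly_per_100").to_csv(outdir / "qaly_per_100.csv", index=False)
    render_table(results, "management_cost").to_csv(
        outdir / "management_cost.csv", index=False
    )
    render_table(results, "sensitivity").to_csv(outdir / "sensitivity.csv", index=False)

    plane = pd.DataFrame(
        [
            {
                "delta_effect": results["cea"]["delta_effect"],
                "delta_cost": results["cea"]["delta_cost"],
                "quadrant": results["cea"]["quadrant"],
            }
        ]
    )
    plane.to_csv(outdir / "ce_plane.csv", index=False)
    (outdir / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    (outdir / "run.log").write_text(
        "crccea run\nconfig: "
        + json.dumps(results["config"], sort_keys=True)
        + f"\nseed: {results['config']['seed']}\n"
    )
    logger.info("report bundle written to %s (new arm %s vs %s)", outdir, new, comp)


def render_table(results: dict, layout: str) -> pd.DataFrame:
    """Render one stage's results in a published-table layout (money and
    years at 2 dp, thousands separators on money)."""
    if layout not in LAYOUTS:
        raise ConfigurationError(f"unknown layout {layout!r}")
    if not results:
        raise InvalidInputError("empty results")
    comp = results["config"]["comparator_arm"]
    new = results["config"]["new_arm"]

    if layout == "cost":
        comps_comp = results["cost"][comp]["components"]
        comps_new = results["cost"][new]["components"]
        rows = [
            {
                "component": name,
                comp: _money(comps_comp[name]),
                new: _money(comps_new[name]),
                "difference": _money(comps_new[name] - comps_comp[name]),
            }
            for name in comps_comp
        ]
        rows.append(
            {
                "component": "total",
                comp: _money(results["cost"][comp]["total"]),
                new: _money(results["cost"][new]["total"]),
                "difference": _money(results["cost"]["difference_total"]),
            }
        )
        return pd.DataFrame(rows)

    if layout == "effectiveness":
        rows = []
        for arm in (comp, new):
            e = results["effectiveness"][arm]
            for stage_name in STAGES:
                rows.append(
                    {
                        "arm": arm,
                        "stage": stage_name,
                        "ly": f"{e['per_stage_ly'][stage_name]:.2f}",
                        "qaly": f"{e['per_stage_qaly'][stage_name]:.2f}",
                    }
                )
            rows.append(
                {
                    "arm": arm,
                    "stage": "total",
                    "ly": f"{e['total_ly']:.2f}",
                    "qaly": f"{e['total_qaly']:.2f}",
                }
            )
            rows.append(
                {
                    "arm": arm,
                    "stage": "per_patient",
                    "ly": f"{e['per_patient_ly']:.2f}",
                    "qaly": f"{e['per_patient_qaly']:.2f}",
                }
            )
        return pd.DataFrame(rows)

    if layout == "cea_summary":
        rows = []
        for item, getter in (
            ("LYs gained", lambda a: f"{results['effectiveness'][a]['per_patient_ly']:.2f}"),
            (
                "QALYs gained",
                lambda a: f"{results['effectiveness'][a]['per_patient_qaly']:.2f}",
            ),
            ("Provider cost (USD)", lambda a: _money(results["cost"][a]["total"])),
            ("Cost per LY (USD)", lambda a: _money(results["cea"]["cost_per_ly"][a])),
            (
                "Cost per QALY (USD)",
                lambda a: _money(results["cea"]["cost_per_qaly"][a]),
            ),
        ):
            rows.append({"item": item, comp: getter(comp), new: getter(new)})
        return pd.DataFrame(rows)

    if layout == "qaly_per_100":
        rows = []
        for stage_name in STAGES:
            row = {"stage": stage_name}
            for arm in (comp, new):
                e = results["effectiveness"][arm]
                row[f"{arm}_qaly_per_100"] = f"{e['per_stage_qaly'][stage_name]:.2f}"
            rows.append(row)
        rows.append(
            {
                "stage": "total",
                f"{comp}_qaly_per_100": f"{results['effectiveness'][comp]['total_qaly']:.2f}",
                f"{new}_qaly_per_100": f"{results['effectiveness'][new]['total_qaly']:.2f}",
            }
        )
        return pd.DataFrame(rows)

    if layout == "management_cost":
        rows = [
            {
                "item": "Total cost of managing CRC patients",
                comp: _money(results["cea"]["management_cost"][comp]),
                new: _money(results["cea"]["management_cost"][new]),
            },
            {
                "item": "ICER (USD per QALY)",
                comp: "",
                new: _money(results["cea"]["icer"]),
            },
            {"item": "Dominance", comp: "", new: results["cea"]["dominance"]},
        ]
        return pd.DataFrame(rows)

    # sensitivity
    rows = []
    for item, key, fmt in (
        ("Mean provider cost (USD)", "provider_cost", _money),
        ("Life-years (LYs) gained", "ly", lambda x: f"{x:.2f}"),
        ("QALYs gained", "qaly", lambda x: f"{x:.2f}"),
    ):
        for arm in (comp, new):
            row = {"item": item, "arm": arm}
            for sc in results["sensitivity"]:
                row[sc["label"]] = fmt(sc["per_arm"][arm][key])
            rows.append(row)
    diff_row = {"item": "Mean provider cost (USD) difference", "arm": "both"}
    for sc in results["sensitivity"]:
        diff_row[sc["label"]] = _money(sc["cost_difference"])
    rows.append(diff_row)
    return pd.DataFrame(rows)
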