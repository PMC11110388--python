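"""End-to-end orchestration: simulate -> sample -> classify -> triage ->
estimate -> report.

A run is fully described by a :class:`RunConfig` (population parameters,
tool specs, reference-standard config, index test, sub-cohort size, age
strata, CI method, seed).  ``run_pipeline`` executes the six stages, writes
tidy CSV outputs, ROC/stratified SVG plots, and a machine-readable manifest
with the resolved config and a content hash per output file; fixed
(config, seed) gives byte-identical bundles.

Seeds: one master seed; child seeds for the population draw and the
sub-cohort draw are derived by fixed offsets so each stage is independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
from pydantic import BaseModel

from .accuracy import (
    DEFAULT_AGE_BIN_EDGES,
    DiagnosticAccuracyModel,
    build_two_by_two,
    estimate_accuracy,
    estimate_prevalence,
    posttest_probability,
    round_half_up,
    stratified_accuracy,
)
from .cohort import generate_parent_cohort
from .config import PopulationConfig, population_config
from .datasets import packaged_tool_paths
from .errors import ConfigurationError
from .plots import plot_age_stratified, plot_roc_points
from .reference import (
    DEFAULT_REFERENCE_CONFIG,
    classify_record,
    load_reference_config,
)
from .rules import evaluate_tool_cumulative, load_tool_spec
from .sampling import (
    apply_complete_case_filter,
    draw_case_cohort_sample,
    link_records,
)

INDEX_TESTS = ("prealert_mtc", "destination_mtc")
_INDEX_COLUMNS = {"prealert_mtc": "provider_prealert_mtc", "destination_mtc": "destination_mtc"}
REFERENCE_STANDARDS = (
    "consensus_positive",
    "iss16",
    "urgent_interventions",
    "consensus_no_open_fractures",
)

# fixed offsets deriving per-stage child seeds from the master seed
_POPULATION_SEED_OFFSET = 0
_SUBCOHORT_SEED_OFFSET = 1


class RunConfig(BaseModel):
    n_incidents: int = 20_000
    subcohort_size: int = 2_000
    seed: int = 0
    index_test: str = "prealert_mtc"
    ci_method: str = "wilson"
    age_bin_edges: Sequence[float] = DEFAULT_AGE_BIN_EDGES
    population_overrides: dict = {}
    tool_paths: Optional[Dict[str, str]] = None  # None -> packaged fixtures
    reference_config_path: Optional[str] = None
    output_dir: str = "triage_run"

    def model_post_init(self, __context) -> None:
        if self.index_test not in INDEX_TESTS:
            raise ValueError(f"index_test must be one of {INDEX_TESTS}")
        if self.subcohort_size > self.n_incidents:
            raise ValueError("subcohort_size cannot exceed n_incidents")


@dataclass
class StageLog:
    stage: str
    counts: Dict[str, int] = field(default_factory=dict)


@dataclass
class RunResult:
    """In-memory view of a completed pipeline run."""

    analysis: pd.DataFrame
    prevalence: float
    prevalence_ci: tuple
    overall: "object"
    per_service: list
    per_age: list
    cumulative: Dict[str, list]
    sensitivity_matrix: pd.DataFrame
    stage_logs: List[StageLog]
    output_dir: Optional[Path] = None
    manifest: Optional[dict] = None


def _analysis_frame(records, provenance, truth, reference_config, tools) -> pd.DataFrame:
    rows = []
    for r in records:
        ref = classify_record(r, reference_config)
        member = provenance[r.record_id]
        row = {
            "record_id": r.record_id,
            "age_years": r.age_years,
            "sex": r.sex,
            "service": r.service,
            "mechanism": r.mechanism,
            "mode": r.mode,
            "provider_prealert_mtc": r.provider_prealert_mtc,
            "destination_mtc": r.destination_mtc,
            "in_subcohort": member.in_subcohort,
            "is_case": member.is_case,
            "truth": truth[r.record_id],
            "iss": ref.iss,
            "consensus_positive": ref.consensus_positive,
            "consensus_domains": "|".join(sorted(ref.domains)),
            "iss16": ref.iss16,
            "urgent_interventions": ref.urgent_interventions,
            "consensus_no_open_fractures": ref.consensus_no_open_fractures,
        }
        for tool in tools:
            ev = evaluate_tool_cumulative(r, tool)
            for depth, flag in ev.cumulative.items():
                row[f"{tool.service_label}_cum{depth}"] = flag
            row[f"{tool.service_label}_mandatory"] = ev.final_mandatory
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> RunResult:
    """Execute the six analysis stages; optionally write the report bundle."""
    logs: List[StageLog] = []

    # stage 1 — simulate the parent cohort
    pop = population_config(
        n_incidents=config.n_incidents,
        seed=config.seed + _POPULATION_SEED_OFFSET,
        **config.population_overrides,
    )
    cohort = generate_parent_cohort(pop)
    logs.append(StageLog("simulate", {"n_incidents": len(cohort)}))

    # stage 2 — case-cohort sampling, deterministic linkage, complete cases
    sample = draw_case_cohort_sample(
        cohort.records, config.subcohort_size, cohort.truth,
        seed=config.seed + _SUBCOHORT_SEED_OFFSET,
    )
    by_id = {r.record_id: r for r in cohort.records}
    sub_set = set(sample.subcohort)
    outside_cases = [by_id[rid] for rid in sample.cases if rid not in sub_set]
    matched_cases, linkage = link_records(outside_cases, cohort.records)
    analysis_records = [by_id[rid] for rid in sample.subcohort] + matched_cases
    kept, cc_log = apply_complete_case_filter(analysis_records)
    logs.append(StageLog("sample", {
        "subcohort": len(sample.subcohort),
        "cases": len(sample.cases),
        "cases_outside_subcohort": len(outside_cases),
        "cases_linked": linkage.n_matched,
        "cases_unlinked": linkage.n_cases - linkage.n_matched,
        "analysis_before_complete_case": cc_log.n_in,
        "analysis_complete_case": cc_log.n_out,
        **{f"removed_{k}": v for k, v in sorted(cc_log.removed_by_field.items())},
    }))

    # stages 3+4 — reference-standard classification and tool evaluation
    if config.reference_config_path:
        ref_config = load_reference_config(config.reference_config_path)
    else:
        ref_config = DEFAULT_REFERENCE_CONFIG
    tool_paths = config.tool_paths if config.tool_paths is not None else packaged_tool_paths()
    tools = [load_tool_spec(p) for p in tool_paths.values()]
    frame = _analysis_frame(kept, sample.provenance(), cohort.truth, ref_config, tools)
    logs.append(StageLog("classify", {
        "n": len(frame),
        "consensus_positive": int(frame["consensus_positive"].sum()),
        **{f"{s}_positive": int(frame[s].sum()) for s in REFERENCE_STANDARDS[1:]},
    }))
    logs.append(StageLog("triage", {"n_tools": len(tools)}))

    # stage 5 — estimation
    index_col = _INDEX_COLUMNS[config.index_test]
    sub = frame[frame["in_subcohort"]]
    prevalence, prev_ci = estimate_prevalence(
        sub["consensus_positive"].to_numpy(), config.ci_method
    )
    overall = estimate_accuracy(
        build_two_by_two(frame[index_col], frame["consensus_positive"]),
        config.ci_method, stratum_label="overall",
    )
    per_service, _ = stratified_accuracy(
        frame, index_col, "consensus_positive", by="group", ci_method=config.ci_method
    )
    per_age, _ = stratified_accuracy(
        frame, index_col, "consensus_positive", by="age",
        bin_edges=config.age_bin_edges, ci_method=config.ci_method,
    )

    cumulative: Dict[str, list] = {}
    roc_tables = []
    for tool in tools:
        depths = sorted(
            int(c[len(tool.service_label) + 4:])
            for c in frame.columns
            if c.startswith(f"{tool.service_label}_cum")
        )
        results = []
        rows = []
        for depth in depths:
            t = build_two_by_two(
                frame[f"{tool.service_label}_cum{depth}"], frame["consensus_positive"]
            )
            res = estimate_accuracy(
                t, config.ci_method, stratum_label=f"{tool.service_label} steps 1-{depth}"
            )
            results.append(res)
            rows.append({
                "tool": tool.service_label, "point": f"steps 1-{depth}", "depth": depth,
                "fpr": 1 - res.specificity, "sensitivity": res.sensitivity,
            })
        obs = frame[frame["service"] == tool.service_label]
        if obs["consensus_positive"].any() and (~obs["consensus_positive"]).any():
            t = build_two_by_two(obs[index_col], obs["consensus_positive"])
            res = estimate_accuracy(
                t, config.ci_method,
                stratum_label=f"{tool.service_label} observed decisions",
            )
            results.append(res)
            rows.append({
                "tool": tool.service_label, "point": "observed decisions",
                "depth": len(depths) + 1,
                "fpr": 1 - res.specificity, "sensitivity": res.sensitivity,
            })
        cumulative[tool.service_label] = results
        roc_tables.append(pd.DataFrame(rows))

    # sensitivity analyses: every reference standard x both index tests
    matrix_rows = []
    for standard in REFERENCE_STANDARDS:
        for test, col in _INDEX_COLUMNS.items():
            t = build_two_by_two(frame[col], frame[standard])
            res = estimate_accuracy(
                t, config.ci_method, stratum_label=f"{standard}/{test}"
            )
            matrix_rows.append({
                "reference_standard": standard, "index_test": test,
                **res.to_dict(),
            })
    sensitivity_matrix = pd.DataFrame(matrix_rows)
    logs.append(StageLog("estimate", {
        "n_analysis": len(frame),
        "n_subcohort": len(sub),
    }))

    result = RunResult(
        analysis=frame, prevalence=prevalence, prevalence_ci=prev_ci,
        overall=overall, per_service=per_service, per_age=per_age,
        cumulative=cumulative, sensitivity_matrix=sensitivity_matrix,
        stage_logs=logs,
    )
    if write_outputs:
        _write_bundle(result, config, pop, roc_tables)
    return result


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def characterise_sample(frame: pd.DataFrame) -> pd.DataFrame:
    """Descriptive sample characteristics by reference-standard status."""
    rows = []
    for status, sub in (("positive", frame[frame["consensus_positive"]]),
                        ("negative", frame[~frame["consensus_positive"]])):
        if len(sub) == 0:
            continue
        rows.append({"status": status, "variable": "n", "value": len(sub)})
        rows.append({"status": status, "variable": "age_median",
                     "value": float(sub["age_years"].median())})
        rows.append({"status": status, "variable": "female_pct",
                     "value": round_half_up(100 * (sub["sex"] == "female").mean(), 1)})
        for mech, share in sub["mechanism"].value_counts(normalize=True).items():
            rows.append({"status": status, "variable": f"mechanism_{mech}_pct",
                         "value": round_half_up(100 * share, 1)})
        if status == "positive":
            rows.append({"status": status, "variable": "iss_median",
                         "value": float(sub["iss"].median())})
    return pd.DataFrame(rows)


def _results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def _write_bundle(result: RunResult, config: RunConfig, pop: PopulationConfig,
                  roc_tables) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    files["analysis_set.csv"] = result.analysis
    files["sample_characteristics.csv"] = characterise_sample(result.analysis)
    files["observed_accuracy.csv"] = _results_frame(
        [result.overall] + result.per_service
    )
    files["age_stratified_accuracy.csv"] = _results_frame(result.per_age)
    files["cumulative_step_accuracy.csv"] = pd.concat(
        [_results_frame(v) for v in result.cumulative.values()], ignore_index=True
    )
    files["sensitivity_analyses.csv"] = result.sensitivity_matrix
    for name, frame in files.items():
        frame.to_csv(out / name, index=False, float_format="%.10g")

    salt = str(config.seed)
    plot_roc_points(roc_tables, out / "roc_points.svg", seed_salt=salt)
    if result.per_age:
        plot_age_stratified(result.per_age, out / "age_stratified.svg", seed_salt=salt)

    summary = {
        "prevalence_subcohort": result.prevalence,
        "prevalence_ci": list(result.prevalence_ci),
        "posttest_prob_positive": posttest_probability(result.prevalence, result.overall.lr_pos),
        "posttest_prob_negative": posttest_probability(result.prevalence, result.overall.lr_neg),
        "overall": result.overall.to_dict(),
        "stage_logs": [{"stage": s.stage, "counts": s.counts} for s in result.stage_logs],
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    output_names = sorted(list(files) + ["roc_points.svg", "run_summary.json"]
                          + (["age_stratified.svg"] if result.per_age else []))
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "population_config": json.loads(pop.model_dump_json()),
        "seed": config.seed,
        "outputs": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in output_names
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    result.output_dir = out
    result.manifest = manifest


def accuracy_from_counts(counts: pd.DataFrame, ci_method: str = "wilson") -> pd.DataFrame:
    """Recompute accuracy metrics from a counts table (tool, n, tp, fp, tn, fn).

    Accepts any frame with tp/fp/tn/fn columns; extra columns are ignored.
    Returns one row of recomputed metrics per input row.
    """
    needed = {"tp", "fp", "tn", "fn"}
    if not needed <= set(counts.columns):
        raise ConfigurationError(f"counts table must have columns {sorted(needed)}")
    label_col = next((c for c in ("tool_name", "tool", "label") if c in counts.columns), None)
    rows = []
    for _, row in counts.iterrows():
        res = DiagnosticAccuracyModel.from_counts(
            int(row["tp"]), int(row["fp"]), int(row["tn"]), int(row["fn"]),
            stratum_label=str(row[label_col]) if label_col else "counts",
        ).fit(ci_method=ci_method)
        rows.append(res.to_dict(digits=2))
    return pd.DataFrame(rows)
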