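"""Declarative step-wise triage tools and their evaluation against records.

English ambulance-service major-trauma triage tools are checklists of
physiological and injury variables.  In grouped tools the variables are
organised into four steps — physiology (1) and anatomical injury (2) are
mandatory, indicating bypass/pre-alert when positive; mechanism of injury (3)
and special circumstances (4) are discretionary.  Ungrouped tools are a
single flat checklist.

Tools are loaded from YAML/JSON documents, validated against a schema, and
evaluated cumulatively: ``cumulative(k)`` is the OR over all criteria in
steps 1..k, so over any labelled sample sensitivity is non-decreasing and
specificity non-increasing in step depth.

Physiology criteria compare the first recorded value; *sustained* criteria
require two or more consecutive recorded values meeting the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .errors import ConfigurationError, MissingDataError
from .records import IncidentRecord, MECHANISMS

PHYSIOLOGY_VARIABLES = ("SBP", "RR", "SpO2", "GCS")
SET_VARIABLES = ("mechanism", "injury_pattern", "special_circumstance")
VARIABLES = PHYSIOLOGY_VARIABLES + ("age",) + SET_VARIABLES

Comparator = Literal["<", "<=", ">", ">=", "==", "in"]

_NUMERIC_OPS = {
    "<": lambda v, t: v < t,
    "<=": lambda v, t: v <= t,
    ">": lambda v, t: v > t,
    ">=": lambda v, t: v >= t,
    "==": lambda v, t: v == t,
}


class TriageCriterion(BaseModel):
    variable: Literal[
        "SBP", "RR", "SpO2", "GCS", "age", "mechanism", "injury_pattern",
        "special_circumstance",
    ]
    comparator: Comparator
    threshold: Union[float, int, str, List[str]]
    sustained: bool = False
    description: str = ""

    @model_validator(mode="after")
    def _consistent(self):
        numeric = self.variable in PHYSIOLOGY_VARIABLES or self.variable == "age"
        if self.sustained and self.variable not in PHYSIOLOGY_VARIABLES:
            raise ValueError(
                f"criterion on {self.variable}: sustained=true is only valid for "
                f"physiological variables {PHYSIOLOGY_VARIABLES}"
            )
        if numeric:
            if self.comparator == "in" or isinstance(self.threshold, (str, list)):
                raise ValueError(
                    f"criterion on {self.variable}: numeric variable requires a "
                    f"numeric comparator and threshold"
                )
        else:
            if self.comparator == "in":
                if not isinstance(self.threshold, list) or not self.threshold:
                    raise ValueError(
                        f"criterion on {self.variable}: 'in' requires a non-empty "
                        f"category list threshold"
                    )
            elif self.comparator == "==":
                if not isinstance(self.threshold, str):
                    raise ValueError(
                        f"criterion on {self.variable}: '==' requires a single "
                        f"category string threshold"
                    )
            else:
                raise ValueError(
                    f"criterion on {self.variable}: categorical variables only "
                    f"support '==' and 'in'"
                )
        if self.variable == "mechanism":
            cats = self.threshold if isinstance(self.threshold, list) else [self.threshold]
            unknown = set(cats) - set(MECHANISMS)
            if unknown:
                raise ValueError(
                    f"criterion on mechanism: unknown categories {sorted(unknown)}"
                )
        return self

    def identity(self) -> str:
        return f"{self.variable}{self.comparator}{self.threshold}" + (
            "[sustained]" if self.sustained else ""
        )


StepLabel = Literal["physiology", "anatomy", "mechanism", "special_circumstances", "ungrouped"]


class TriageStep(BaseModel):
    index: int = Field(ge=1, le=4)
    label: StepLabel
    mandatory: bool
    criteria: List[TriageCriterion] = Field(min_length=1)


class TriageToolSpec(BaseModel):
    service_label: str
    grouped: bool
    steps: List[TriageStep] = Field(min_length=1)

    @model_validator(mode="after")
    def _step_structure(self):
        indices = [s.index for s in self.steps]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("steps: indices must be strictly increasing")
        if self.grouped:
            for s in self.steps:
                if s.index <= 2 and not s.mandatory:
                    raise ValueError(f"steps: step {s.index} must be mandatory in a grouped tool")
                if s.index >= 3 and s.mandatory:
                    raise ValueError(f"steps: step {s.index} must be discretionary in a grouped tool")
        else:
            if len(self.steps) != 1:
                raise ValueError("steps: an ungrouped tool has exactly one step")
            if self.steps[0].label != "ungrouped":
                raise ValueError("steps: the single step of an ungrouped tool is labelled 'ungrouped'")
        return self

    @property
    def max_depth(self) -> int:
        return len(self.steps)


def load_tool_spec(source) -> TriageToolSpec:
    """Load and validate a tool spec from a path, YAML text, or mapping."""
    if isinstance(source, (str, Path)):
        text = str(source)
        is_path = "\n" not in text and Path(text).suffix in (".yaml", ".yml", ".json")
        doc = yaml.safe_load(Path(text).read_text() if is_path else text)
    else:
        doc = source
    try:
        return TriageToolSpec(**doc)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def dump_tool_spec(tool: TriageToolSpec) -> str:
    return yaml.safe_dump(tool.model_dump(), sort_keys=False)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class CriterionResult:
    criterion_id: str
    passed: bool
    value: object
    evidence: str


@dataclass
class TriageEvaluation:
    service_label: str
    per_criterion: Dict[int, List[CriterionResult]]  # step index -> results
    per_step: Dict[int, bool]
    cumulative: Dict[int, bool]  # depth (1-based position in step order) -> bool
    final_mandatory: bool
    final_all_steps: bool


def derive_injury_patterns(record: IncidentRecord) -> frozenset:
    """Anatomy-step pattern tags derived from the coded injuries."""
    tags = set()
    regions = {i.region for i in record.injuries}
    if record.mode == "penetrating":
        tags.add("penetrating")
        if regions & {"thorax", "abdomen"}:
            tags.add("penetrating_torso")
        if regions & {"head", "face"}:
            tags.add("penetrating_head_neck")
    if any(i.open_fracture for i in record.injuries):
        tags.add("open_fracture")
    if len({i.region for i in record.injuries if i.severity >= 2}) >= 2:
        tags.add("two_or_more_body_regions")
    if any(i.region == "thorax" and i.severity >= 3 for i in record.injuries):
        tags.add("major_chest_injury")
    return frozenset(tags)


def _sustained_run(values: Sequence[float], op, threshold) -> Optional[int]:
    """Index of the first run of >=2 consecutive values meeting the threshold."""
    for i in range(len(values) - 1):
        if op(values[i], threshold) and op(values[i + 1], threshold):
            return i
    return None


def evaluate_criterion(record: IncidentRecord, criterion: TriageCriterion) -> CriterionResult:
    """Evaluate one criterion, returning the outcome and its evidence.

    Raises :class:`MissingDataError` (never a silent False) when the
    variable the criterion needs is absent from the record.
    """
    cid = criterion.identity()
    if criterion.variable in PHYSIOLOGY_VARIABLES:
        sig = criterion.variable.lower()
        series = record.signal_series(sig)
        if not series:
            raise MissingDataError(f"{record.record_id}: no vitals recorded for criterion {cid}")
        if any(v is None for v in series):
            raise MissingDataError(f"{record.record_id}: missing {criterion.variable} for criterion {cid}")
        op = _NUMERIC_OPS[criterion.comparator]
        if criterion.sustained:
            idx = _sustained_run(series, op, criterion.threshold)
            passed = idx is not None
            evidence = (
                f"sustained run at measurements {idx},{idx + 1}: "
                f"{series[idx]},{series[idx + 1]}" if passed else f"no sustained run in {series}"
            )
            return CriterionResult(cid, passed, series, evidence)
        value = series[0]
        passed = bool(op(value, criterion.threshold))
        return CriterionResult(cid, passed, value, f"first recorded value {value} (measurement 0)")
    if criterion.variable == "age":
        value = record.age_years
        passed = bool(_NUMERIC_OPS[criterion.comparator](value, criterion.threshold))
        return CriterionResult(cid, passed, value, f"age {value}")
    # categorical variables
    if criterion.variable == "mechanism":
        values = {record.mechanism}
    elif criterion.variable == "injury_pattern":
        values = set(derive_injury_patterns(record))
    else:
        values = set(record.special_circumstances)
    cats = (
        set(criterion.threshold)
        if isinstance(criterion.threshold, list)
        else {criterion.threshold}
    )
    hits = values & cats
    return CriterionResult(
        cid, bool(hits), sorted(values),
        f"matched {sorted(hits)}" if hits else f"no match among {sorted(values)}",
    )


def evaluate_tool_cumulative(record: IncidentRecord, tool: TriageToolSpec) -> TriageEvaluation:
    """Evaluate every criterion of every step and roll up cumulatively."""
    per_criterion: Dict[int, List[CriterionResult]] = {}
    per_step: Dict[int, bool] = {}
    for step in tool.steps:
        results = [evaluate_criterion(record, c) for c in step.criteria]
        per_criterion[step.index] = results
        per_step[step.index] = any(r.passed for r in results)
    cumulative: Dict[int, bool] = {}
    acc = False
    for depth, step in enumerate(tool.steps, start=1):
        acc = acc or per_step[step.index]
        cumulative[depth] = acc
    final_mandatory = any(per_step[s.index] for s in tool.steps if s.mandatory)
    return TriageEvaluation(
        service_label=tool.service_label,
        per_criterion=per_criterion,
        per_step=per_step,
        cumulative=cumulative,
        final_mandatory=final_mandatory,
        final_all_steps=acc,
    )
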