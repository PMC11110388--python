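"""Triage-rule engine: schema validation, criterion semantics, cumulative OR."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trauma_triage import (
    ConfigurationError,
    MissingDataError,
    TriageCriterion,
    dump_tool_spec,
    evaluate_criterion,
    evaluate_tool_cumulative,
    load_tool_spec,
)
from trauma_triage.records import VitalsMeasurement
from trauma_triage.rules import PHYSIOLOGY_VARIABLES, derive_injury_patterns
from trauma_triage.records import Injury

from conftest import fuzz_record, make_record


# ---------------------------------------------------------------------------
# loading / validation
# ---------------------------------------------------------------------------

def test_packaged_grouped_tool_structure(tools):
    by_label = {t.service_label: t for t in tools}
    las = by_label["LAS"]
    assert las.grouped and len(las.steps) == 4
    assert [s.mandatory for s in las.steps] == [True, True, False, False]
    swas = by_label["SWAS"]
    assert not swas.grouped and len(swas.steps) == 1
    assert swas.steps[0].label == "ungrouped"


def test_sustained_only_for_physiology():
    with pytest.raises(ConfigurationError, match="sustained"):
        load_tool_spec({
            "service_label": "X", "grouped": False,
            "steps": [{"index": 1, "label": "ungrouped", "mandatory": True,
                       "criteria": [{"variable": "mechanism", "comparator": "in",
                                     "threshold": ["gunshot"], "sustained": True}]}],
        })


@pytest.mark.parametrize("criterion", [
    {"variable": "SBP", "comparator": "in", "threshold": ["low"]},
    {"variable": "mechanism", "comparator": "<", "threshold": 3},
    {"variable": "mechanism", "comparator": "in", "threshold": ["warp_drive"]},
    {"variable": "injury_pattern", "comparator": "in", "threshold": []},
])
def test_comparator_threshold_mismatch_rejected(criterion):
    with pytest.raises(ConfigurationError):
        load_tool_spec({
            "service_label": "X", "grouped": False,
            "steps": [{"index": 1, "label": "ungrouped", "mandatory": True,
                       "criteria": [criterion]}],
        })


def test_empty_step_rejected():
    with pytest.raises(ConfigurationError):
        load_tool_spec({"service_label": "X", "grouped": False,
                        "steps": [{"index": 1, "label": "ungrouped",
                                   "mandatory": True, "criteria": []}]})


def test_round_trip_is_identity(tools):
    for tool in tools:
        assert load_tool_spec(dump_tool_spec(tool)) == tool


# ---------------------------------------------------------------------------
# criterion semantics
# ---------------------------------------------------------------------------

def _crit(**kw):
    return TriageCriterion(**kw)


def test_first_value_rule():
    r = make_record(sbp=(85.0, 110.0), rr=(16.0, 16.0), spo2=(98.0, 98.0), gcs=(15, 15))
    res = evaluate_criterion(r, _crit(variable="SBP", comparator="<", threshold=90))
    assert res.passed and res.value == 85.0
    # later hypotension does not count for a first-value criterion
    r2 = make_record(sbp=(110.0, 85.0), rr=(16.0, 16.0), spo2=(98.0, 98.0), gcs=(15, 15))
    assert not evaluate_criterion(r2, _crit(variable="SBP", comparator="<", threshold=90)).passed


@pytest.mark.parametrize("series,expected", [
    ((31.0, 25.0, 33.0), False),
    ((31.0, 33.0, 25.0), True),
    ((25.0, 31.0, 33.0), True),
    ((31.0,), False),  # a single reading can never be sustained
])
def test_sustained_requires_consecutive_run(series, expected):
    r = make_record(
        rr=series, sbp=tuple(120.0 for _ in series),
        spo2=tuple(98.0 for _ in series), gcs=tuple(15 for _ in series),
    )
    res = evaluate_criterion(r, _crit(variable="RR", comparator=">", threshold=29, sustained=True))
    assert res.passed is expected


def test_boundary_comparators_exact():
    r = make_record(gcs=(13,))
    assert evaluate_criterion(r, _crit(variable="GCS", comparator="<=", threshold=13)).passed
    assert not evaluate_criterion(r, _crit(variable="GCS", comparator="<", threshold=13)).passed
    r15 = make_record(gcs=(15,))
    assert not evaluate_criterion(r15, _crit(variable="GCS", comparator="<=", threshold=13)).passed


def test_missing_variable_is_an_error_not_false():
    r = make_record()
    r.vitals = [VitalsMeasurement(time_min=0.0, sbp=120.0, rr=16.0, spo2=98.0, gcs=None)]
    with pytest.raises(MissingDataError):
        evaluate_criterion(r, _crit(variable="GCS", comparator="<=", threshold=13))
    r.vitals = []
    with pytest.raises(MissingDataError):
        evaluate_criterion(r, _crit(variable="SBP", comparator="<", threshold=90))


def test_categorical_membership():
    r = make_record(mechanism="fall_gt_1m",
                    injuries=[Injury("thorax", 3), Injury("extremities", 2, True)])
    assert evaluate_criterion(
        r, _crit(variable="mechanism", comparator="in", threshold=["fall_gt_1m", "gunshot"])
    ).passed
    assert evaluate_criterion(
        r, _crit(variable="injury_pattern", comparator="in", threshold=["open_fracture"])
    ).passed
    assert not evaluate_criterion(
        r, _crit(variable="special_circumstance", comparator="in", threshold=["anticoagulant_use"])
    ).passed
    assert "major_chest_injury" in derive_injury_patterns(r)


# ---------------------------------------------------------------------------
# cumulative evaluation
# ---------------------------------------------------------------------------

def test_step2_positive_propagates_to_deeper_depths(tools):
    las = next(t for t in tools if t.service_label == "LAS")
    r = make_record(mechanism="cutting_piercing_stabbing",
                    injuries=[Injury("abdomen", 2)], age=30.0)
    ev = evaluate_tool_cumulative(r, las)
    assert not ev.per_step[1]
    assert ev.per_step[2]  # penetrating injury pattern
    assert [ev.cumulative[d] for d in sorted(ev.cumulative)] == [False, True, True, True]
    assert ev.final_mandatory


def test_all_negative_record(tools):
    r = make_record(age=30.0)
    for tool in tools:
        ev = evaluate_tool_cumulative(r, tool)
        assert not any(ev.cumulative.values())
        assert not ev.final_mandatory and not ev.final_all_steps


def test_evidence_reported_for_true_criteria():
    r = make_record(sbp=(80.0, 78.0), rr=(16.0, 16.0), spo2=(98.0, 98.0), gcs=(15, 15))
    res = evaluate_criterion(r, _crit(variable="SBP", comparator="<", threshold=90, sustained=True))
    assert res.passed
    assert "80" in res.evidence and "78" in res.evidence


# ---------------------------------------------------------------------------
# oracle equivalence and invariance properties
# ---------------------------------------------------------------------------

def _naive_criterion(record, c):
    """Independent brute-force evaluation of one criterion."""
    ops = {"<": np.less, "<=": np.less_equal, ">": np.greater,
           ">=": np.greater_equal, "==": np.equal}
    if c.variable in PHYSIOLOGY_VARIABLES:
        series = record.signal_series(c.variable.lower())
        if c.sustained:
            hits = [bool(ops[c.comparator](v, c.threshold)) for v in series]
            return any(hits[i] and hits[i + 1] for i in range(len(hits) - 1))
        return bool(ops[c.comparator](series[0], c.threshold))
    if c.variable == "age":
        return bool(ops[c.comparator](record.age_years, c.threshold))
    if c.variable == "mechanism":
        values = {record.mechanism}
    elif c.variable == "injury_pattern":
        values = set(derive_injury_patterns(record))
    else:
        values = set(record.special_circumstances)
    cats = set(c.threshold) if isinstance(c.threshold, list) else {c.threshold}
    return bool(values & cats)


def test_engine_matches_naive_evaluator_on_fuzzed_records(tools):
    rng = np.random.default_rng(2024)
    for i in range(1000):
        r = fuzz_record(rng, f"F{i}")
        for tool in tools:
            ev = evaluate_tool_cumulative(r, tool)
            acc = False
            for depth, step in enumerate(tool.steps, start=1):
                step_naive = any(_naive_criterion(r, c) for c in step.criteria)
                assert ev.per_step[step.index] == step_naive, (r.record_id, tool.service_label)
                acc = acc or step_naive
                assert ev.cumulative[depth] == acc
            naive_mandatory = any(
                any(_naive_criterion(r, c) for c in s.criteria)
                for s in tool.steps if s.mandatory
            )
            assert ev.final_mandatory == naive_mandatory


def test_cumulative_monotone_and_order_independent(tools):
    rng = np.random.default_rng(7)
    las = next(t for t in tools if t.service_label == "LAS")
    shuffled = las.model_copy(deep=True)
    for step in shuffled.steps:
        step.criteria = list(reversed(step.criteria))
    for i in range(200):
        r = fuzz_record(rng, f"P{i}")
        ev = evaluate_tool_cumulative(r, las)
        flags = [ev.cumulative[d] for d in sorted(ev.cumulative)]
        assert flags == sorted(flags)  # False <= True monotone
        ev2 = evaluate_tool_cumulative(r, shuffled)
        assert ev.per_step == ev2.per_step and ev.cumulative == ev2.cumulative


@given(st.lists(st.integers(min_value=3, max_value=15), min_size=1, max_size=6))
def test_sustained_implies_first_value_somewhere(gcs_series):
    """If a sustained GCS criterion fires, at least two consecutive readings
    individually meet the threshold."""
    r = make_record(
        gcs=tuple(gcs_series),
        sbp=tuple(120.0 for _ in gcs_series),
        rr=tuple(16.0 for _ in gcs_series),
        spo2=tuple(98.0 for _ in gcs_series),
    )
    c = TriageCriterion(variable="GCS", comparator="<=", threshold=13, sustained=True)
    res = evaluate_criterion(r, c)
    runs = [gcs_series[i] <= 13 and gcs_series[i + 1] <= 13 for i in range(len(gcs_series) - 1)]
    assert res.passed == any(runs)
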