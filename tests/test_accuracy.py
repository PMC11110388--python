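"""Accuracy estimation: 2x2 tables, CIs, likelihood ratios, Bayes, strata."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from trauma_triage import (
    CaseCohortPPVWarning,
    ConfigurationError,
    DiagnosticAccuracyModel,
    TwoByTwo,
    UndefinedMetricError,
    build_two_by_two,
    estimate_accuracy,
    estimate_prevalence,
    posttest_probability,
    round_half_up,
    stratified_accuracy,
)


# ---------------------------------------------------------------------------
# 2x2 construction
# ---------------------------------------------------------------------------

def test_perfect_agreement_has_no_errors():
    flags = np.array([True] * 4 + [False] * 6)
    t = build_two_by_two(flags, flags)
    assert (t.tp, t.fp, t.tn, t.fn) == (4, 0, 6, 0)


def test_all_negative_index():
    idx = np.zeros(10, dtype=bool)
    ref = np.array([True] * 3 + [False] * 7)
    t = build_two_by_two(idx, ref)
    assert t.tp == 0 and t.fp == 0 and t.fn == 3 and t.tn == 7


def test_misaligned_or_missing_flags_rejected():
    with pytest.raises(ConfigurationError):
        build_two_by_two([True, False], [True])
    with pytest.raises(ConfigurationError):
        build_two_by_two(pd.array([True, None], dtype="boolean"), [True, False])


@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
def test_two_by_two_matches_direct_enumeration(pairs):
    idx = [a for a, _ in pairs]
    ref = [b for _, b in pairs]
    t = build_two_by_two(idx, ref)
    assert t.tp == sum(a and b for a, b in pairs)
    assert t.fp == sum(a and not b for a, b in pairs)
    assert t.fn == sum(not a and b for a, b in pairs)
    assert t.tn == sum(not a and not b for a, b in pairs)
    assert t.n == len(pairs)


# ---------------------------------------------------------------------------
# point estimates and identities
# ---------------------------------------------------------------------------

def test_overall_decision_metrics_at_two_decimals():
    res = DiagnosticAccuracyModel.from_counts(446, 95, 1703, 513).fit()
    assert round_half_up(res.sensitivity) == 0.47
    assert round_half_up(res.specificity) == 0.95
    assert round_half_up(res.lr_pos) == 8.80
    assert round_half_up(res.lr_neg) == 0.56


def test_high_specificity_service_lr():
    res = DiagnosticAccuracyModel.from_counts(66, 9, 422, 190).fit()
    assert round_half_up(res.lr_pos) == 12.35


@given(st.tuples(st.integers(1, 500), st.integers(1, 500),
                 st.integers(1, 500), st.integers(1, 500)))
def test_lr_identities_exact(counts):
    tp, fp, tn, fn = counts
    res = DiagnosticAccuracyModel.from_counts(tp, fp, tn, fn).fit()
    assert math.isclose(res.lr_pos * (1 - res.specificity), res.sensitivity,
                        rel_tol=0, abs_tol=1e-12)
    assert math.isclose(res.lr_neg * res.specificity, 1 - res.sensitivity,
                        rel_tol=0, abs_tol=1e-12)
    assert res.sensitivity_ci[0] <= res.sensitivity <= res.sensitivity_ci[1]
    assert res.specificity_ci[0] <= res.specificity <= res.specificity_ci[1]


def test_empty_margins_raise_named_errors():
    with pytest.raises(UndefinedMetricError, match="sensitivity"):
        DiagnosticAccuracyModel.from_counts(0, 5, 5, 0).fit()
    with pytest.raises(UndefinedMetricError, match="specificity"):
        DiagnosticAccuracyModel.from_counts(5, 0, 0, 5).fit()


def test_perfect_specificity_gives_flagged_infinite_lr():
    res = DiagnosticAccuracyModel.from_counts(8, 0, 50, 2).fit()
    assert math.isinf(res.lr_pos)
    assert res.degenerate
    assert math.isinf(res.lr_pos_ci[1]) and res.lr_pos_ci[0] > 0


def test_round_half_up_at_printed_precision():
    assert round_half_up(6.125) == 6.13
    assert round_half_up(0.465) == 0.47
    assert round_half_up(0.464999) == 0.46
    assert round_half_up(3.1349, 1) == 3.1


# ---------------------------------------------------------------------------
# prevalence and Bayes
# ---------------------------------------------------------------------------

def test_subcohort_prevalence_printing():
    flags = np.array([True] * 54 + [False] * (1722 - 54))
    p, (lo, hi) = estimate_prevalence(flags)
    assert round_half_up(100 * p, 1) == 3.1
    assert lo < p < hi


def test_zero_positive_prevalence_one_sided():
    p, (lo, hi) = estimate_prevalence(np.zeros(200, dtype=bool))
    assert p == 0.0 and lo == 0.0 and hi > 0.0


def test_empty_subcohort_rejected():
    with pytest.raises(UndefinedMetricError):
        estimate_prevalence([])


def test_prevalence_ci_coverage():
    """~95% of binomial sub-cohort draws cover the true prevalence."""
    rng = np.random.default_rng(17)
    truth = 0.031
    n = 1800
    covered = 0
    reps = 1000
    ks = rng.binomial(n, truth, size=reps)
    for k in ks:
        flags = np.zeros(n, dtype=bool)
        flags[:k] = True
        _, (lo, hi) = estimate_prevalence(flags)
        covered += lo <= truth <= hi
    assert 0.93 <= covered / reps <= 0.98


def test_sens_spec_ci_coverage():
    """Wilson intervals achieve ~95% coverage for sensitivity at fixed truth."""
    rng = np.random.default_rng(23)
    sens_true, n_pos, n_neg = 0.47, 959, 1798
    reps = 1000
    tps = rng.binomial(n_pos, sens_true, size=reps)
    covered = 0
    for tp in tps:
        res = DiagnosticAccuracyModel.from_counts(int(tp), 95, n_neg - 95, n_pos - int(tp)).fit()
        covered += res.sensitivity_ci[0] <= sens_true <= res.sensitivity_ci[1]
    assert 0.93 <= covered / reps <= 0.98


def test_posttest_identity_at_lr_one():
    for p in (0.01, 0.031, 0.5, 0.9):
        assert posttest_probability(p, 1.0) == pytest.approx(p, abs=1e-15)


def test_posttest_boundary_prevalence_rejected():
    with pytest.raises(ConfigurationError):
        posttest_probability(0.0, 2.0)
    with pytest.raises(ConfigurationError):
        posttest_probability(1.0, 2.0)


@given(st.tuples(st.integers(1, 300), st.integers(1, 300),
                 st.integers(1, 300), st.integers(1, 300)))
def test_posttest_equals_ppv_on_simple_random_sample(counts):
    """On a simple random sample, Bayes' rule with the sample prevalence and
    LR+ reproduces tp/(tp+fp) exactly."""
    tp, fp, tn, fn = counts
    res = DiagnosticAccuracyModel.from_counts(tp, fp, tn, fn, design="simple_random").fit()
    prevalence = (tp + fn) / (tp + fp + tn + fn)
    assert posttest_probability(prevalence, res.lr_pos) == pytest.approx(
        res.ppv(), abs=1e-12
    )


def test_ppv_warns_under_case_cohort_design():
    res = DiagnosticAccuracyModel.from_counts(446, 95, 1703, 513).fit()
    with pytest.warns(CaseCohortPPVWarning):
        inflated = res.ppv()
    # case enrichment inflates the direct PPV far above the population value
    assert inflated > posttest_probability(0.031, res.lr_pos)


# ---------------------------------------------------------------------------
# stratified estimation
# ---------------------------------------------------------------------------

def _toy_frame():
    rng = np.random.default_rng(3)
    n = 400
    age = rng.uniform(0, 100, n)
    ref = rng.random(n) < 0.3
    idx = np.where(ref, rng.random(n) < 0.7, rng.random(n) < 0.1)
    return pd.DataFrame({"age_years": age, "index": idx, "ref": ref,
                         "service": rng.choice(["A", "B"], n)})


def test_stratified_tables_pool_to_whole_sample():
    frame = _toy_frame()
    results, empties = stratified_accuracy(
        frame, "index", "ref", by="age", bin_edges=(0, 50, math.inf)
    )
    whole = build_two_by_two(frame["index"], frame["ref"])
    pooled_tp = sum(r.table.tp for r in results)
    pooled_n = sum(r.table.n for r in results) + sum(e.n for e in empties)
    assert pooled_tp == whole.tp and pooled_n == whole.n


def test_overlapping_strata_rejected():
    with pytest.raises(ConfigurationError):
        stratified_accuracy(_toy_frame(), "index", "ref", by="age",
                            bin_edges=(0, 50, 40, math.inf))


def test_empty_reference_margin_reported_without_estimate():
    frame = pd.DataFrame({
        "age_years": [10.0, 12.0, 70.0, 75.0],
        "index": [True, False, True, False],
        "ref": [False, False, True, False],
    })
    results, empties = stratified_accuracy(frame, "index", "ref", by="age",
                                           bin_edges=(0, 16, math.inf))
    assert [r.stratum_label for r in results] == [">=16"]
    assert [e.stratum_label for e in empties] == ["<16"]
    assert empties[0].n == 2 and empties[0].n_positive == 0


def test_group_stratification_by_service():
    frame = _toy_frame()
    results, _ = stratified_accuracy(frame, "index", "ref", by="group")
    assert sorted(r.stratum_label for r in results) == ["A", "B"]
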