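"""Diagnostic accuracy estimation for triage decisions and tools.

The central objects follow the Model/Results idiom: build a
:class:`DiagnosticAccuracyModel` from aligned index-test and
reference-standard flags (or directly from 2x2 counts), call
:meth:`~DiagnosticAccuracyModel.fit`, and read estimates, confidence
intervals, likelihood ratios and Bayesian post-test probabilities off the
returned :class:`DiagnosticAccuracyResults`.

Under the case-cohort design the analysis is unweighted: sensitivity comes
from all cases, specificity from sub-cohort negatives, and prevalence from
the random sub-cohort alone.  Because the case-enriched table's column
margins do not reflect population prevalence, a predictive value read
directly off such a table is inflated — the results object warns and the
supported route is a likelihood ratio combined with the sub-cohort
prevalence (pre-test odds x LR = post-test odds).

Confidence intervals: Wilson score by default (Wald optional) for
proportions; the log-transform (Simel) method for likelihood ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import CaseCohortPPVWarning, ConfigurationError, UndefinedMetricError

_Z = 1.959963984540054  # standard normal 97.5% quantile


def round_half_up(x: float, digits: int = 2) -> float:
    """Round with ties away from zero at the given precision (so 6.125 -> 6.13),
    matching how printed clinical tables are rounded."""
    x = float(x)
    if math.isinf(x) or math.isnan(x):
        return x
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TwoByTwo:
    """Cross-tabulation of an index test against a reference standard."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


def build_two_by_two(index_flags, reference_flags) -> TwoByTwo:
    """Exact cross-tabulation of aligned, complete boolean columns."""
    idx = np.asarray(index_flags)
    ref = np.asarray(reference_flags)
    if idx.shape != ref.shape or idx.ndim != 1:
        raise ConfigurationError(
            f"index and reference flags must be aligned 1-d columns "
            f"(got shapes {idx.shape} and {ref.shape})"
        )
    for name, col in (("index", idx), ("reference", ref)):
        if pd.isna(col).any():
            raise ConfigurationError(f"{name} flags contain missing values; "
                                     "apply the complete-case filter first")
    idx = idx.astype(bool)
    ref = ref.astype(bool)
    return TwoByTwo(
        tp=int((idx & ref).sum()),
        fp=int((idx & ~ref).sum()),
        tn=int((~idx & ~ref).sum()),
        fn=int((~idx & ref).sum()),
    )


def _proportion_ci(count: int, nobs: int, method: str) -> Tuple[float, float]:
    sm_method = {"wilson": "wilson", "wald": "normal"}.get(method)
    if sm_method is None:
        raise ConfigurationError(f"unknown ci_method {method!r} (use wilson or wald)")
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method=sm_method)
    return float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def _lr_ci(lr: float, tp: int, fn: int, fp: int, tn: int, positive: bool) -> Tuple[float, float]:
    """Simel log-method interval for a likelihood ratio.

    For LR+ the variance of log LR is 1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn);
    for LR- replace tp<->fn and fp<->tn.  Degenerate cells give one-sided or
    undefined limits handled by the caller.
    """
    if positive:
        a, m1, b, m2 = tp, tp + fn, fp, fp + tn
    else:
        a, m1, b, m2 = fn, tp + fn, tn, fp + tn
    if lr == 0 or math.isinf(lr) or a == 0 or b == 0:
        return (float("nan"), float("inf") if math.isinf(lr) else float("nan"))
    se = math.sqrt(1 / a - 1 / m1 + 1 / b - 1 / m2)
    return (lr * math.exp(-_Z * se), lr * math.exp(_Z * se))


class DiagnosticAccuracyModel:
    """Accuracy of a binary index test against a binary reference standard.

    Parameters
    ----------
    index_flags, reference_flags
        Aligned boolean columns (one element per incident), or ``None`` when
        constructed via :meth:`from_counts`.
    design
        ``"case_cohort"`` (default) or ``"simple_random"``; controls the
        predictive-value warning on the fitted results.
    stratum_label
        Free-text label carried onto the results (e.g. a service name or an
        age band).
    """

    def __init__(self, index_flags, reference_flags, *, design: str = "case_cohort",
                 stratum_label: str = "overall"):
        self.table = build_two_by_two(index_flags, reference_flags)
        self.design = design
        self.stratum_label = stratum_label

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int, *,
                    design: str = "case_cohort", stratum_label: str = "overall"):
        model = cls.__new__(cls)
        model.table = TwoByTwo(tp=tp, fp=fp, tn=tn, fn=fn)
        model.design = design
        model.stratum_label = stratum_label
        return model

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, index_col: str, reference_col: str,
                       **kwargs):
        return cls(data[index_col].to_numpy(), data[reference_col].to_numpy(), **kwargs)

    def fit(self, ci_method: str = "wilson") -> "DiagnosticAccuracyResults":
        t = self.table
        if t.n_positive == 0:
            raise UndefinedMetricError(
                "sensitivity undefined: no reference-positive records (tp+fn=0)"
            )
        if t.n_negative == 0:
            raise UndefinedMetricError(
                "specificity undefined: no reference-negative records (fp+tn=0)"
            )
        sens = t.tp / t.n_positive
        spec = t.tn / t.n_negative
        sens_ci = _proportion_ci(t.tp, t.n_positive, ci_method)
        spec_ci = _proportion_ci(t.tn, t.n_negative, ci_method)
        degenerate = []
        if spec == 1.0:
            lr_pos = float("inf")
            degenerate.append("lr_pos infinite: specificity = 1 (fp = 0); one-sided CI")
            # one-sided lower bound from continuity-corrected counts
            cc = (t.tp + 0.5) / (t.n_positive + 1) / ((t.fp + 0.5) / (t.n_negative + 1))
            se = math.sqrt(1 / (t.tp + 0.5) + 1 / 0.5)
            lr_pos_ci = (cc * math.exp(-_Z * se), float("inf"))
        else:
            lr_pos = sens / (1 - spec)
            lr_pos_ci = _lr_ci(lr_pos, t.tp, t.fn, t.fp, t.tn, positive=True)
        if spec == 0.0:
            lr_neg = float("inf")
            degenerate.append("lr_neg infinite: specificity = 0")
            lr_neg_ci = (float("nan"), float("inf"))
        else:
            lr_neg = (1 - sens) / spec
            lr_neg_ci = _lr_ci(lr_neg, t.tp, t.fn, t.fp, t.tn, positive=False)
        return DiagnosticAccuracyResults(
            table=t, sensitivity=sens, sensitivity_ci=sens_ci,
            specificity=spec, specificity_ci=spec_ci,
            lr_pos=lr_pos, lr_pos_ci=lr_pos_ci,
            lr_neg=lr_neg, lr_neg_ci=lr_neg_ci,
            n=t.n, stratum_label=self.stratum_label, design=self.design,
            ci_method=ci_method, degenerate=tuple(degenerate),
        )


@dataclass
class DiagnosticAccuracyResults:
    """Fitted accuracy estimates for one 2x2 table."""

    table: TwoByTwo
    sensitivity: float
    sensitivity_ci: Tuple[float, float]
    specificity: float
    specificity_ci: Tuple[float, float]
    lr_pos: float
    lr_pos_ci: Tuple[float, float]
    lr_neg: float
    lr_neg_ci: Tuple[float, float]
    n: int
    stratum_label: str
    design: str
    ci_method: str
    degenerate: Tuple[str, ...] = ()

    def ppv(self) -> float:
        """tp/(tp+fp).  Warns under case-cohort sampling, where the column
        margins are case-enriched and this over-states the predictive value."""
        if self.design == "case_cohort":
            warnings.warn(
                "PPV computed from a case-cohort 2x2 table is inflated by case "
                "enrichment; combine a likelihood ratio with the sub-cohort "
                "prevalence instead",
                CaseCohortPPVWarning,
                stacklevel=2,
            )
        denom = self.table.tp + self.table.fp
        if denom == 0:
            raise UndefinedMetricError("PPV undefined: no index-positive records")
        return self.table.tp / denom

    def posttest_positive(self, prevalence: float) -> float:
        """P(disease | positive test) at the given pre-test prevalence."""
        return posttest_probability(prevalence, self.lr_pos)

    def posttest_negative(self, prevalence: float) -> float:
        """P(disease | negative test) at the given pre-test prevalence."""
        return posttest_probability(prevalence, self.lr_neg)

    def roc_point(self) -> Tuple[float, float]:
        return (1 - self.specificity, self.sensitivity)

    def to_dict(self, digits: Optional[int] = None) -> Dict[str, float]:
        rnd = (lambda x: round_half_up(x, digits)) if digits is not None else (lambda x: x)
        t = self.table
        return {
            "stratum": self.stratum_label, "n": self.n,
            "tp": t.tp, "fp": t.fp, "tn": t.tn, "fn": t.fn,
            "sensitivity": rnd(self.sensitivity),
            "sensitivity_lcl": rnd(self.sensitivity_ci[0]),
            "sensitivity_ucl": rnd(self.sensitivity_ci[1]),
            "specificity": rnd(self.specificity),
            "specificity_lcl": rnd(self.specificity_ci[0]),
            "specificity_ucl": rnd(self.specificity_ci[1]),
            "lr_pos": rnd(self.lr_pos),
            "lr_pos_lcl": rnd(self.lr_pos_ci[0]),
            "lr_pos_ucl": rnd(self.lr_pos_ci[1]),
            "lr_neg": rnd(self.lr_neg),
            "lr_neg_lcl": rnd(self.lr_neg_ci[0]),
            "lr_neg_ucl": rnd(self.lr_neg_ci[1]),
        }

    def summary(self) -> str:
        t = self.table
        lines = [
            "Diagnostic accuracy" + (f" — {self.stratum_label}" if self.stratum_label else ""),
            "=" * 58,
            f"design: {self.design:<22} ci method: {self.ci_method}",
            f"n = {self.n}   tp={t.tp} fp={t.fp} tn={t.tn} fn={t.fn}",
            "-" * 58,
            f"{'metric':<14}{'estimate':>10}{'95% LCL':>12}{'95% UCL':>12}",
        ]
        for name, est, ci in (
            ("sensitivity", self.sensitivity, self.sensitivity_ci),
            ("specificity", self.specificity, self.specificity_ci),
            ("LR+", self.lr_pos, self.lr_pos_ci),
            ("LR-", self.lr_neg, self.lr_neg_ci),
        ):
            lines.append(f"{name:<14}{est:>10.3f}{ci[0]:>12.3f}{ci[1]:>12.3f}")
        for note in self.degenerate:
            lines.append(f"note: {note}")
        lines.append("=" * 58)
        return "\n".join(lines)


def estimate_accuracy(table: TwoByTwo, ci_method: str = "wilson",
                      stratum_label: str = "overall",
                      design: str = "case_cohort") -> DiagnosticAccuracyResults:
    """Functional wrapper: fit a model directly from a 2x2 table."""
    return DiagnosticAccuracyModel.from_counts(
        table.tp, table.fp, table.tn, table.fn,
        design=design, stratum_label=stratum_label,
    ).fit(ci_method=ci_method)


def estimate_prevalence(subcohort_truth_flags, ci_method: str = "wilson"
                        ) -> Tuple[float, Tuple[float, float]]:
    """Reference-standard prevalence in the random sub-cohort.

    Must be fed sub-cohort flags only — cases recruited from outside the
    sub-cohort would inflate the estimate.  Unweighted simple proportion
    with a binomial interval.
    """
    flags = np.asarray(subcohort_truth_flags, dtype=bool)
    if flags.size == 0:
        raise UndefinedMetricError("prevalence undefined: empty sub-cohort")
    k = int(flags.sum())
    return k / flags.size, _proportion_ci(k, flags.size, ci_method)


def posttest_probability(prevalence: float, lr: float) -> float:
    """Bayes on the odds scale: post-test odds = pre-test odds x LR."""
    if not 0 < prevalence < 1:
        raise ConfigurationError(f"prevalence must lie strictly in (0,1), got {prevalence}")
    if lr < 0:
        raise ConfigurationError(f"likelihood ratio must be >= 0, got {lr}")
    if math.isinf(lr):
        return 1.0
    odds = prevalence / (1 - prevalence) * lr
    return odds / (1 + odds)


# ---------------------------------------------------------------------------
# Stratified and cumulative-step analyses
# ---------------------------------------------------------------------------

#: Age strata: children, then 10-year adult bands, ending in an open 90+ band.
DEFAULT_AGE_BIN_EDGES = (0, 16, 30, 40, 50, 60, 70, 80, 90, math.inf)


def age_bin_labels(edges: Sequence[float]) -> List[str]:
    labels = []
    for lo, hi in zip(edges, edges[1:]):
        if lo == 0:
            labels.append(f"<{hi:g}")
        elif math.isinf(hi):
            labels.append(f">={lo:g}")
        else:
            labels.append(f"{lo:g}-{hi:g}")
    return labels


@dataclass
class EmptyStratum:
    stratum_label: str
    n: int
    n_positive: int
    n_negative: int


def stratified_accuracy(
    data: pd.DataFrame,
    index_col: str,
    reference_col: str,
    by: str = "age",
    age_col: str = "age_years",
    bin_edges: Sequence[float] = DEFAULT_AGE_BIN_EDGES,
    group_col: str = "service",
    ci_method: str = "wilson",
) -> Tuple[List[DiagnosticAccuracyResults], List[EmptyStratum]]:
    """Accuracy per age band (``by="age"``) or per categorical group
    (``by="group"``, e.g. ambulance service).

    Strata with an empty reference margin are reported with their counts but
    carry no estimate.  The age bands must partition the age axis.
    """
    if by == "age":
        edges = list(bin_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigurationError("age bin edges must be strictly increasing "
                                     "(overlapping strata are not a partition)")
        labels = age_bin_labels(edges)
        keys = pd.cut(data[age_col], bins=edges, labels=labels,
                      right=False, include_lowest=True)
        ordered = labels
    elif by == "group":
        keys = data[group_col]
        ordered = sorted(keys.unique())
    else:
        raise ConfigurationError(f"unknown stratification {by!r} (use age or group)")

    results: List[DiagnosticAccuracyResults] = []
    empties: List[EmptyStratum] = []
    for label in ordered:
        sub = data[np.asarray(keys == label)]
        if len(sub) == 0:
            empties.append(EmptyStratum(str(label), 0, 0, 0))
            continue
        t = build_two_by_two(sub[index_col].to_numpy(), sub[reference_col].to_numpy())
        if t.n_positive == 0 or t.n_negative == 0:
            empties.append(EmptyStratum(str(label), t.n, t.n_positive, t.n_negative))
            continue
        results.append(estimate_accuracy(t, ci_method, stratum_label=str(label)))
    return results, empties


def cumulative_step_series(
    evaluations,
    reference_flags,
    tool_label: str = "",
    observed_flags=None,
    ci_method: str = "wilson",
) -> Tuple[List[DiagnosticAccuracyResults], pd.DataFrame]:
    """Accuracy at each cumulative step depth of one triage tool.

    Parameters
    ----------
    evaluations
        One :class:`~trauma_triage.rules.TriageEvaluation` per record.
    reference_flags
        Aligned reference-standard positivity.
    observed_flags
        Optional aligned observed provider decisions, appended as a final
        ROC point for comparison with the theoretical tool.

    Returns the per-depth results (sensitivity non-decreasing and
    specificity non-increasing by construction of the cumulative OR) and a
    tidy ROC-point table of (1-specificity, sensitivity) ordered by depth.
    """
    evaluations = list(evaluations)
    ref = np.asarray(reference_flags, dtype=bool)
    if len(evaluations) != ref.size:
        raise ConfigurationError("evaluations and reference flags must align")
    depths = sorted(evaluations[0].cumulative) if evaluations else []
    results = []
    rows = []
    for depth in depths:
        flags = np.array([e.cumulative[depth] for e in evaluations], dtype=bool)
        t = build_two_by_two(flags, ref)
        label = f"{tool_label} depth {depth}".strip()
        res = estimate_accuracy(t, ci_method, stratum_label=label)
        results.append(res)
        rows.append({
            "tool": tool_label, "point": f"steps 1-{depth}", "depth": depth,
            "fpr": 1 - res.specificity, "sensitivity": res.sensitivity,
        })
    if observed_flags is not None:
        t = build_two_by_two(np.asarray(observed_flags, dtype=bool), ref)
        res = estimate_accuracy(t, ci_method, stratum_label=f"{tool_label} observed decisions")
        rows.append({
            "tool": tool_label, "point": "observed decisions", "depth": len(depths) + 1,
            "fpr": 1 - res.specificity, "sensitivity": res.sensitivity,
        })
        results.append(res)
    return results, pd.DataFrame(rows)
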