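"""Case-cohort sampling design, deterministic record linkage, complete cases.

The analysis set of a diagnostic case-cohort study is the union of (a) a
random sub-cohort drawn irrespective of reference-standard status and (b)
every reference-standard-positive case in the parent cohort, the latter
identified in an external registry and linked back to the ambulance record
deterministically on the patient report form number.  Positives drawn into
the sub-cohort appear once, flagged with both provenances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .records import IncidentRecord


@dataclass
class SampleMember:
    record_id: str
    in_subcohort: bool
    is_case: bool


@dataclass
class LinkageReport:
    n_cases: int = 0
    n_matched: int = 0
    n_missing_key: int = 0
    n_ambiguous_key: int = 0
    n_unmatched_key: int = 0

    @property
    def match_rate(self) -> float:
        return self.n_matched / self.n_cases if self.n_cases else float("nan")


@dataclass
class CaseCohortSample:
    """The analysis set with per-record sampling provenance."""

    subcohort: List[str]
    cases: List[str]
    members: List[SampleMember]
    linkage_report: Optional[LinkageReport] = None

    @property
    def analysis_ids(self) -> List[str]:
        return [m.record_id for m in self.members]

    def provenance(self) -> Dict[str, SampleMember]:
        return {m.record_id: m for m in self.members}


def draw_case_cohort_sample(
    cohort: Sequence[IncidentRecord],
    subcohort_size: int,
    truth: Mapping[str, bool],
    seed: int,
) -> CaseCohortSample:
    """Random sub-cohort plus all truth-positive cases, deduplicated.

    Parameters
    ----------
    cohort
        Parent-cohort records.
    subcohort_size
        Number of records sampled uniformly without replacement,
        irrespective of status.
    truth
        record_id -> reference-standard positivity.
    seed
        Seed for the sub-cohort draw.
    """
    ids = [r.record_id for r in cohort]
    if subcohort_size > len(ids):
        raise ConfigurationError(
            f"subcohort_size {subcohort_size} exceeds cohort size {len(ids)}"
        )
    if subcohort_size <= 0:
        raise ConfigurationError("subcohort_size must be positive")
    rng = np.random.default_rng(seed)
    sub = sorted(rng.choice(len(ids), size=subcohort_size, replace=False).tolist())
    subcohort = [ids[i] for i in sub]
    sub_set = set(subcohort)
    cases = [rid for rid in ids if truth.get(rid, False)]
    case_set = set(cases)
    members = [
        SampleMember(rid, in_subcohort=rid in sub_set, is_case=rid in case_set)
        for rid in ids
        if rid in sub_set or rid in case_set
    ]
    return CaseCohortSample(subcohort=subcohort, cases=cases, members=members)


def link_records(
    cases: Iterable[IncidentRecord],
    ambulance_records: Iterable[IncidentRecord],
) -> tuple[List[IncidentRecord], LinkageReport]:
    """Deterministic exact-key matching on ``report_form_id``.

    Cases with a missing key, a key duplicated within either source, or a
    key absent from the ambulance data are reported unmatched; no fuzzy
    matching is attempted.
    """
    amb_keys: Dict[str, int] = {}
    for r in ambulance_records:
        if r.report_form_id:
            amb_keys[r.report_form_id] = amb_keys.get(r.report_form_id, 0) + 1
    case_list = list(cases)
    case_key_counts: Dict[str, int] = {}
    for r in case_list:
        if r.report_form_id:
            case_key_counts[r.report_form_id] = case_key_counts.get(r.report_form_id, 0) + 1

    report = LinkageReport(n_cases=len(case_list))
    matched: List[IncidentRecord] = []
    for r in case_list:
        key = r.report_form_id
        if not key:
            report.n_missing_key += 1
        elif case_key_counts[key] > 1 or amb_keys.get(key, 0) > 1:
            report.n_ambiguous_key += 1
        elif key not in amb_keys:
            report.n_unmatched_key += 1
        else:
            matched.append(r)
            report.n_matched += 1
    return matched, report


#: Signals whose first recorded value must be present for the analysis.
DEFAULT_REQUIRED_SIGNALS = ("sbp", "rr", "spo2", "gcs")


@dataclass
class CompleteCaseLog:
    n_in: int = 0
    n_out: int = 0
    removed_by_field: Dict[str, int] = field(default_factory=dict)


def apply_complete_case_filter(
    records: Iterable[IncidentRecord],
    required_signals: Sequence[str] = DEFAULT_REQUIRED_SIGNALS,
) -> tuple[List[IncidentRecord], CompleteCaseLog]:
    """Drop records missing any field required to evaluate the index test,
    triage tools or reference standard; attribute each removal to the first
    missing field.

    A record needs a non-empty vitals series and a non-missing value of each
    required signal in every recorded measurement (sustained criteria scan
    the whole series).
    """
    log = CompleteCaseLog()
    kept: List[IncidentRecord] = []
    for r in records:
        log.n_in += 1
        reason = None
        if not r.vitals:
            reason = "vitals"
        else:
            for sig in required_signals:
                if any(v is None for v in r.signal_series(sig)):
                    reason = sig
                    break
        if reason is None:
            kept.append(r)
        else:
            log.removed_by_field[reason] = log.removed_by_field.get(reason, 0) + 1
    log.n_out = len(kept)
    return kept, log
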