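"""Reference standards for major trauma.

The primary ("consensus") reference standard defines patients who would
benefit from expedited Major Trauma Centre care through four domains:

1. need for critical (urgent trauma) interventions;
2. significant individual anatomical injuries requiring specialist care;
3. a burden of multiple injuries benefiting from multidisciplinary care;
4. patient characteristics indicating capacity to benefit from specialist
   care.

Three secondary standards are derived alongside it: Injury Severity Score
(ISS) >= 16; the critical-interventions domain alone; and the consensus
standard re-evaluated with open-fracture-triggered injury rules removed.

The exact clinical criterion lists behind the domains live in consensus
documents, not here; they are modelled as configurable predicate lists with
a documented default set so the classifier is faithful in structure and
auditable, while real deployments supply the authentic lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Set, Tuple

import yaml
from pydantic import BaseModel, Field, ValidationError

from .errors import ConfigurationError
from .records import AIS_REGIONS, IncidentRecord, Injury

#: The six classic ISS body regions.
ISS_REGIONS = AIS_REGIONS


def compute_iss(injuries) -> int:
    """Injury Severity Score: sum of squares of the highest AIS severity in
    each of the three most severely injured body regions.

    By convention any AIS severity-6 (currently untreatable) injury sets
    ISS to the maximum of 75.  No injuries gives 0.
    """
    maxima = {}
    for inj in injuries:
        sev = int(inj.severity)
        if not 1 <= sev <= 6:
            raise ConfigurationError(f"AIS severity must be in 1..6, got {sev}")
        if sev == 6:
            return 75
        maxima[inj.region] = max(maxima.get(inj.region, 0), sev)
    top = sorted(maxima.values(), reverse=True)[:3]
    return int(sum(s * s for s in top))


class SignificantInjuryRule(BaseModel):
    """One predicate over a single injury: region membership, a minimum AIS
    severity, and optionally an open-fracture requirement."""

    regions: Optional[List[str]] = None  # None = any region
    min_severity: int = Field(ge=1, le=6)
    require_open: bool = False
    description: str = ""

    def matches(self, injury: Injury) -> bool:
        if self.regions is not None and injury.region not in self.regions:
            return False
        if injury.severity < self.min_severity:
            return False
        if self.require_open and not injury.open_fracture:
            return False
        return True


class MultipleInjuryRule(BaseModel):
    """Multiple-injury burden: at least ``min_regions`` distinct body regions
    each carrying an injury of severity >= ``min_severity``."""

    min_regions: int = 2
    min_severity: int = 3

    def matches(self, injuries) -> bool:
        regions = {i.region for i in injuries if i.severity >= self.min_severity}
        return len(regions) >= self.min_regions


class CapacityToBenefitRule(BaseModel):
    """Capacity to benefit from specialist care: an age band combined with a
    minimum injury severity.  Requires at least one coded injury by default
    (configurable; whether the domain can fire with no coded injury is an
    open clinical question)."""

    min_age: Optional[float] = 65.0
    max_age: Optional[float] = None
    min_severity: int = 3
    require_injury: bool = True

    def matches(self, record: IncidentRecord) -> bool:
        if self.require_injury and not record.injuries:
            return False
        if self.min_age is not None and record.age_years < self.min_age:
            return False
        if self.max_age is not None and record.age_years > self.max_age:
            return False
        return any(i.severity >= self.min_severity for i in record.injuries)


class ReferenceStandardConfig(BaseModel):
    urgent_intervention_set: Set[str]
    significant_injury_rules: List[SignificantInjuryRule] = Field(min_length=1)
    multiple_injury_rule: MultipleInjuryRule = MultipleInjuryRule()
    capacity_to_benefit_rule: CapacityToBenefitRule = CapacityToBenefitRule()
    iss_threshold: int = Field(default=16, ge=0)


DEFAULT_REFERENCE_CONFIG = ReferenceStandardConfig(
    urgent_intervention_set={
        "intubation",
        "thoracostomy",
        "blood_product_transfusion",
        "emergency_surgery",
        "interventional_radiology",
    },
    significant_injury_rules=[
        SignificantInjuryRule(min_severity=3, description="any AIS>=3 injury"),
        SignificantInjuryRule(
            regions=["extremities"], min_severity=2, require_open=True,
            description="open extremity fracture",
        ),
    ],
)


def load_reference_config(path) -> ReferenceStandardConfig:
    doc = yaml.safe_load(open(path).read())
    try:
        return ReferenceStandardConfig(**doc)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


@dataclass
class ReferenceStandardResult:
    """Per-record positivity under the four reference standards."""

    consensus_positive: bool
    domains: FrozenSet[str]
    iss: int
    iss16: bool
    urgent_interventions: bool
    consensus_no_open_fractures: bool


def classify_consensus(
    record: IncidentRecord,
    config: ReferenceStandardConfig,
    include_open_fracture_rules: bool = True,
) -> Tuple[bool, FrozenSet[str]]:
    """Evaluate the four consensus domains; positive iff any holds."""
    domains = set()
    if record.interventions & config.urgent_intervention_set:
        domains.add("critical_interventions")
    rules = config.significant_injury_rules
    if not include_open_fracture_rules:
        rules = [r for r in rules if not r.require_open]
    if any(rule.matches(inj) for rule in rules for inj in record.injuries):
        domains.add("significant_injury")
    if config.multiple_injury_rule.matches(record.injuries):
        domains.add("multiple_injuries")
    if config.capacity_to_benefit_rule.matches(record):
        domains.add("capacity_to_benefit")
    return bool(domains), frozenset(domains)


def classify_record(
    record: IncidentRecord,
    config: ReferenceStandardConfig = DEFAULT_REFERENCE_CONFIG,
) -> ReferenceStandardResult:
    """Classify one record against the primary and secondary standards."""
    positive, domains = classify_consensus(record, config)
    no_open, _ = classify_consensus(record, config, include_open_fracture_rules=False)
    iss = compute_iss(record.injuries)
    return ReferenceStandardResult(
        consensus_positive=positive,
        domains=domains,
        iss=iss,
        iss16=iss >= config.iss_threshold,
        urgent_interventions=bool(record.interventions & config.urgent_intervention_set),
        consensus_no_open_fractures=no_open,
    )
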