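"""Configuration for the synthetic prehospital cohort generator.

The defaults encode the published characteristics of acutely injured patients
conveyed by four English ambulance services: an elderly-skewed, predominantly
blunt-trauma population dominated by ground-level falls, with a low (~3.1%)
prevalence of major trauma meeting the consensus reference standard.  All
distributions are stratified by latent reference-standard status ("positive"
= would benefit from expedited Major Trauma Centre care).

Configs are pydantic models so a YAML/JSON document validates field-by-field,
with errors naming the offending field.
"""

from __future__ import annotations

import json
from typing import Dict, Tuple

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .errors import ConfigurationError
from .records import MECHANISMS

_WEIGHT_TOL = 1e-9


def _check_simplex(name: str, values) -> None:
    vals = list(values)
    if any(v < 0 or v > 1 for v in vals):
        raise ValueError(f"{name}: probabilities must lie in [0,1]")
    if abs(sum(vals) - 1.0) > _WEIGHT_TOL:
        raise ValueError(f"{name}: weights must sum to 1 (got {sum(vals)!r})")


class AgeMixtureParams(BaseModel):
    """Child/adult/elderly mixture for one reference-standard stratum.

    Children and adults are uniform within their band; the elderly band is a
    truncated normal so the upper tail matches observed medians/IQRs.
    """

    weights: Tuple[float, float, float]
    child_band: Tuple[float, float] = (0.0, 16.0)
    adult_band: Tuple[float, float] = (16.0, 65.0)
    elderly_band: Tuple[float, float] = (65.0, 103.0)
    elderly_mu: float = 80.0
    elderly_sigma: float = 11.0

    @field_validator("weights")
    @classmethod
    def _weights_simplex(cls, v):
        _check_simplex("age_mixture.weights", v)
        return v


class VitalsParams(BaseModel):
    """First-measurement distributions and within-record serial drift.

    SBP/RR/SpO2 are truncated normals (mmHg, breaths/min, %); GCS is an
    explicit categorical over 3..15.  Serial measurements follow a bounded
    random walk from the first value, because sustained-physiology triage
    criteria need runs of consecutive values.
    """

    sbp: Tuple[float, float, float, float]  # mu, sigma, lo, hi
    rr: Tuple[float, float, float, float]
    spo2: Tuple[float, float, float, float]
    gcs_probs: Dict[int, float]
    n_measurement_probs: Tuple[float, ...] = (0.35, 0.35, 0.20, 0.10)  # 1..4 readings
    walk_sd: Dict[str, float] = {"sbp": 8.0, "rr": 2.0, "spo2": 1.5, "gcs": 0.3}

    @field_validator("gcs_probs")
    @classmethod
    def _gcs_simplex(cls, v):
        if any(k < 3 or k > 15 for k in v):
            raise ValueError("vitals_params.gcs_probs: keys must be GCS values 3..15")
        _check_simplex("vitals_params.gcs_probs", v.values())
        return v

    @field_validator("n_measurement_probs")
    @classmethod
    def _n_simplex(cls, v):
        _check_simplex("vitals_params.n_measurement_probs", v)
        return v


class InjuryParams(BaseModel):
    """AIS injury generation for one stratum.

    ``region_probs`` are marginal involvement probabilities per AIS body
    region (not a simplex — a patient can injure several regions).
    ``severity_probs`` is the categorical for the severity of each injured
    region.  For positives, ``open_fracture_only_frac`` is the share whose
    qualifying injury is an open extremity fracture (AIS 2, open) rather than
    an AIS>=3 injury; ``open_fracture_prob`` adds open flags to extremity
    injuries of severity >=2.
    """

    region_probs: Dict[str, float]
    severity_probs: Dict[int, float]
    second_injury_prob: float = 0.2
    open_fracture_only_frac: float = 0.0
    open_fracture_prob: float = 0.0
    ensure_min_one_region: bool = False

    @field_validator("region_probs")
    @classmethod
    def _regions_valid(cls, v):
        if any(p < 0 or p > 1 for p in v.values()):
            raise ValueError("injury_params.region_probs: probabilities must be in [0,1]")
        return v

    @field_validator("severity_probs")
    @classmethod
    def _sev_simplex(cls, v):
        if any(k < 1 or k > 6 for k in v):
            raise ValueError("injury_params.severity_probs: severities must be 1..6")
        _check_simplex("injury_params.severity_probs", v.values())
        return v


class ProviderBehaviour(BaseModel):
    """Logistic model of the crew's pre-alert decision.

    P(pre-alert | status, age) = expit(alpha_status + slope_status * (age - 60));
    the intercepts are solved at generation time so the expected whole-sample
    sensitivity and specificity equal the configured targets on the realised
    age distribution.  Negative slopes give the observed spectrum effect:
    sensitivity falls, and specificity rises, from younger to older patients.
    """

    target_sensitivity: float = 0.467
    target_specificity: float = 0.945
    age_slope_sensitivity: float = -0.032  # per year, logit scale
    age_slope_false_positive: float = -0.020
    extra_mtc_conveyance_pos: float = 0.20  # destination index test only
    extra_mtc_conveyance_neg: float = 0.17

    @model_validator(mode="after")
    def _targets_open_unit(self):
        for name in ("target_sensitivity", "target_specificity"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"provider_behaviour.{name}: must lie in (0,1)")
        return self


def _default_mechanism_probs() -> Dict[str, Dict[str, float]]:
    # Raw per-stratum category counts, normalised to exact simplexes.
    pos = {
        "cutting_piercing_stabbing": 56, "gunshot": 1, "fall_gt_1m": 232,
        "fall_lt_1m": 339, "rta_motorcycle": 40, "rta_motor_vehicle": 76,
        "rta_bicycle": 30, "rta_pedestrian": 107, "struck_by_object": 45,
        "struck_by_person": 21, "other_unknown": 12,
    }
    neg = {
        "cutting_piercing_stabbing": 40, "gunshot": 0, "fall_gt_1m": 109,
        "fall_lt_1m": 1274, "rta_motorcycle": 20, "rta_motor_vehicle": 66,
        "rta_bicycle": 22, "rta_pedestrian": 45, "struck_by_object": 85,
        "struck_by_person": 106, "other_unknown": 31,
    }
    out = {}
    for label, counts in (("positive", pos), ("negative", neg)):
        total = sum(counts.values())
        probs = {k: counts[k] / total for k in MECHANISMS}
        # force exact unit sum despite float division
        probs[MECHANISMS[-1]] += 1.0 - sum(probs.values())
        out[label] = probs
    return out


_DEF_GCS_POS = {
    15: 0.62, 14: 0.16, 13: 0.05, 12: 0.03, 11: 0.02, 10: 0.02, 9: 0.015,
    8: 0.015, 7: 0.01, 6: 0.01, 5: 0.01, 4: 0.01, 3: 0.03,
}
_DEF_GCS_NEG = {15: 0.93, 14: 0.04, 13: 0.02, 12: 0.005, 10: 0.003, 8: 0.002}


class PopulationConfig(BaseModel):
    """Full parameterisation of the synthetic parent cohort."""

    n_incidents: int = Field(gt=0)
    prevalence: float = 0.031
    seed: int = 0

    age_mixture: Dict[str, AgeMixtureParams] = {
        "positive": AgeMixtureParams(
            weights=(0.032, 0.512, 0.456), elderly_mu=78.0, elderly_sigma=10.0
        ),
        "negative": AgeMixtureParams(
            weights=(0.066, 0.358, 0.576), elderly_mu=84.0, elderly_sigma=12.0
        ),
    }
    sex_ratio_female: Dict[str, float] = {"positive": 0.415, "negative": 0.532}
    mechanism_probs: Dict[str, Dict[str, float]] = Field(
        default_factory=_default_mechanism_probs
    )
    service_probs: Dict[str, float] = {
        "LAS": 0.226, "SWAS": 0.249, "WMAS": 0.290, "YAS": 0.235,
    }
    vitals_params: Dict[str, VitalsParams] = {
        "positive": VitalsParams(
            sbp=(137.0, 26.7, 40.0, 280.0),
            rr=(19.8, 3.8, 0.0, 60.0),
            spo2=(96.6, 3.6, 0.0, 100.0),
            gcs_probs=_DEF_GCS_POS,
        ),
        "negative": VitalsParams(
            sbp=(142.0, 25.9, 50.0, 260.0),
            rr=(18.0, 3.0, 8.0, 70.0),
            spo2=(97.2, 2.3, 60.0, 100.0),
            gcs_probs=_DEF_GCS_NEG,
        ),
    }
    injury_params: Dict[str, InjuryParams] = {
        "positive": InjuryParams(
            region_probs={
                "head": 0.53, "face": 0.146, "thorax": 0.402, "abdomen": 0.206,
                "extremities": 0.504, "external": 0.33,
            },
            severity_probs={2: 0.30, 3: 0.45, 4: 0.19, 5: 0.06},
            open_fracture_only_frac=0.10,
            open_fracture_prob=0.20,
            ensure_min_one_region=True,
        ),
        "negative": InjuryParams(
            region_probs={
                "head": 0.25, "face": 0.10, "thorax": 0.08, "abdomen": 0.04,
                "extremities": 0.45, "external": 0.30,
            },
            severity_probs={1: 0.70, 2: 0.30},
        ),
    }
    provider_behaviour: ProviderBehaviour = ProviderBehaviour()
    urgent_intervention_prob: Dict[str, float] = {"positive": 0.308, "negative": 0.0}
    hems_prob: Dict[str, float] = {"positive": 0.193, "negative": 0.013}
    id_missingness: float = 0.03
    vitals_missingness: float = 0.02

    @field_validator("prevalence")
    @classmethod
    def _prevalence_open_unit(cls, v):
        if not 0 < v < 1:
            raise ValueError("prevalence: must lie strictly in (0,1)")
        return v

    @field_validator("id_missingness", "vitals_missingness")
    @classmethod
    def _fraction(cls, v, info):
        if not 0 <= v <= 1:
            raise ValueError(f"{info.field_name}: must lie in [0,1]")
        return v

    @field_validator("service_probs")
    @classmethod
    def _service_simplex(cls, v):
        _check_simplex("service_probs", v.values())
        return v

    @field_validator("mechanism_probs")
    @classmethod
    def _mech_simplex(cls, v):
        for status, probs in v.items():
            unknown = set(probs) - set(MECHANISMS)
            if unknown:
                raise ValueError(f"mechanism_probs[{status}]: unknown categories {sorted(unknown)}")
            _check_simplex(f"mechanism_probs[{status}]", probs.values())
        return v

    @model_validator(mode="after")
    def _strata_present(self):
        for name in ("age_mixture", "sex_ratio_female", "mechanism_probs",
                     "vitals_params", "injury_params"):
            keys = set(getattr(self, name))
            if keys != {"positive", "negative"}:
                raise ValueError(f"{name}: must have exactly the strata positive/negative")
        return self


def load_population_config(path) -> PopulationConfig:
    """Read a PopulationConfig from a YAML or JSON document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) if str(path).endswith((".yaml", ".yml")) else json.load(fh)
    try:
        return PopulationConfig(**doc)
    except ValidationError as exc:  # re-raise with the package's error type
        raise ConfigurationError(str(exc)) from exc


def population_config(**overrides) -> PopulationConfig:
    """Construct a config from defaults, raising ConfigurationError on bad fields."""
    try:
        return PopulationConfig(**overrides)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc
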