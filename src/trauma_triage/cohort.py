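"""Synthetic parent-cohort generation.

Each incident gets a latent reference-standard status (major trauma that
would benefit from expedited Major Trauma Centre care, or not), and every
other field is drawn conditional on that status so the stratum marginals
match the study-population targets: elderly-skewed ages, ground-level-fall
dominated mechanisms, stratum-specific vital signs, AIS-coded injuries with
positive-stratum ISS centred on 18, and a crew pre-alert decision whose
whole-sample sensitivity/specificity hit the configured targets with an
age-linked spectrum effect.

The generator is coherent with the default reference-standard classifier:
positives always carry either an AIS>=3 injury or an open extremity
fracture, and negatives never do (severity <=2, closed, no urgent
interventions), so re-classifying generated records recovers the latent
truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .config import PopulationConfig
from .errors import ConfigurationError
from .records import (
    AIS_REGIONS,
    MECHANISMS,
    IncidentRecord,
    Injury,
    VitalsMeasurement,
)

URGENT_INTERVENTIONS = (
    "intubation",
    "thoracostomy",
    "blood_product_transfusion",
    "emergency_surgery",
    "interventional_radiology",
)

ROUTINE_INTERVENTIONS = ("analgesia", "splinting", "wound_dressing")


@dataclass
class ParentCohort:
    """A generated cohort plus its latent reference-standard truth."""

    records: List[IncidentRecord]
    truth: Dict[str, bool]
    config: PopulationConfig = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def truth_array(self) -> np.ndarray:
        return np.array([self.truth[r.record_id] for r in self.records], dtype=bool)


def _draw_ages(rng, params, n):
    comp = rng.choice(3, size=n, p=np.asarray(params.weights) / sum(params.weights))
    ages = np.empty(n)
    for idx, band in enumerate((params.child_band, params.adult_band)):
        m = comp == idx
        ages[m] = rng.uniform(band[0], band[1], m.sum())
    m = comp == 2
    lo, hi = params.elderly_band
    a = (lo - params.elderly_mu) / params.elderly_sigma
    b = (hi - params.elderly_mu) / params.elderly_sigma
    ages[m] = stats.truncnorm.rvs(
        a, b, loc=params.elderly_mu, scale=params.elderly_sigma,
        size=m.sum(), random_state=rng,
    )
    return ages


def _truncnorm(rng, mu, sigma, lo, hi, n):
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


def _calibrate_intercept(ages: np.ndarray, slope: float, target: float) -> float:
    """Solve alpha so mean(expit(alpha + slope*(age-60))) == target."""
    shift = slope * (ages - 60.0)

    def gap(alpha):
        return expit(alpha + shift).mean() - target

    lo, hi = logit(target) - 30.0, logit(target) + 30.0
    return optimize.brentq(gap, lo, hi, xtol=1e-10)


def _draw_injuries(rng, params, positive: bool) -> list[Injury]:
    regions = [r for r in AIS_REGIONS if rng.random() < params.region_probs.get(r, 0.0)]
    if params.ensure_min_one_region and not regions:
        probs = np.array([params.region_probs.get(r, 0.0) for r in AIS_REGIONS])
        regions = [rng.choice(AIS_REGIONS, p=probs / probs.sum())]
    sev_vals = np.array(sorted(params.severity_probs))
    sev_p = np.array([params.severity_probs[s] for s in sev_vals], dtype=float)
    sev_p /= sev_p.sum()
    injuries: list[Injury] = []
    open_fracture_only = positive and rng.random() < params.open_fracture_only_frac
    for region in regions:
        sev = int(rng.choice(sev_vals, p=sev_p))
        if open_fracture_only:
            sev = min(sev, 2)
        open_flag = (
            region == "extremities"
            and sev >= 2
            and rng.random() < params.open_fracture_prob
        )
        injuries.append(Injury(region, sev, open_flag))
        if rng.random() < params.second_injury_prob:
            injuries.append(Injury(region, int(rng.integers(1, sev + 1)), False))
    if positive:
        if open_fracture_only:
            # qualifying injury is the open extremity fracture itself
            if not any(i.region == "extremities" and i.open_fracture for i in injuries):
                injuries.append(Injury("extremities", 2, True))
        elif not any(i.severity >= 3 for i in injuries):
            # guarantee at least one significant (AIS>=3) injury
            region = injuries[0].region if injuries else "head"
            injuries.append(Injury(region, int(rng.choice([3, 4], p=[0.6, 0.4])), False))
    else:
        injuries = [Injury(i.region, min(i.severity, 2), False) for i in injuries]
    return injuries


_MAX_MEASUREMENTS = 4


def _draw_vitals_arrays(rng, vp, k: int):
    """Vectorised first values and random-walk increments for k records."""
    first = {
        "sbp": _truncnorm(rng, *vp.sbp, k),
        "rr": _truncnorm(rng, *vp.rr, k),
        "spo2": _truncnorm(rng, *vp.spo2, k),
    }
    gvals = np.array(sorted(vp.gcs_probs))
    gp = np.array([vp.gcs_probs[g] for g in gvals], dtype=float)
    first["gcs"] = rng.choice(gvals, size=k, p=gp / gp.sum())
    steps = {
        sig: rng.normal(0.0, vp.walk_sd[sig], size=(k, _MAX_MEASUREMENTS - 1))
        for sig in ("sbp", "rr", "spo2", "gcs")
    }
    return first, steps


def _assemble_vitals(vp, first, steps, j: int, missing_gcs_all: bool,
                     n_meas: int) -> list[VitalsMeasurement]:
    sbp, rr, spo2 = first["sbp"][j], first["rr"][j], first["spo2"][j]
    gcs = int(first["gcs"][j])
    out = []
    for k in range(n_meas):
        if k > 0:  # bounded random walk from the first reading
            sbp = min(max(sbp + steps["sbp"][j, k - 1], vp.sbp[2]), vp.sbp[3])
            rr = min(max(rr + steps["rr"][j, k - 1], vp.rr[2]), vp.rr[3])
            spo2 = min(max(spo2 + steps["spo2"][j, k - 1], vp.spo2[2]), 100.0)
            gcs = int(min(max(round(gcs + steps["gcs"][j, k - 1]), 3), 15))
        out.append(
            VitalsMeasurement(
                time_min=float(5 * k),
                sbp=round(float(sbp), 0),
                rr=round(float(rr), 0),
                spo2=round(float(spo2), 0),
                gcs=None if missing_gcs_all else gcs,
            )
        )
    return out


def generate_parent_cohort(config: PopulationConfig) -> ParentCohort:
    """Generate ``config.n_incidents`` incident records.

    Deterministic for a fixed config (the seed is part of the config): two
    calls with identical configs return identical cohorts.
    """
    if not isinstance(config, PopulationConfig):
        raise ConfigurationError("config must be a PopulationConfig")
    rng = np.random.default_rng(config.seed)
    n = config.n_incidents
    status = rng.random(n) < config.prevalence

    ages = np.empty(n)
    for label, mask in (("positive", status), ("negative", ~status)):
        ages[mask] = _draw_ages(rng, config.age_mixture[label], int(mask.sum()))

    female = np.empty(n, dtype=bool)
    mech = np.empty(n, dtype=object)
    for label, mask in (("positive", status), ("negative", ~status)):
        k = int(mask.sum())
        female[mask] = rng.random(k) < config.sex_ratio_female[label]
        probs = np.array([config.mechanism_probs[label][m] for m in MECHANISMS])
        mech[mask] = rng.choice(MECHANISMS, size=k, p=probs / probs.sum())

    services = list(config.service_probs)
    sprobs = np.array([config.service_probs[s] for s in services])
    service = rng.choice(services, size=n, p=sprobs / sprobs.sum())

    n_meas = 1 + rng.choice(
        len(config.vitals_params["negative"].n_measurement_probs),
        size=n,
        p=np.asarray(config.vitals_params["negative"].n_measurement_probs),
    )
    gcs_missing = rng.random(n) < config.vitals_missingness
    id_missing = rng.random(n) < config.id_missingness
    hems = np.empty(n, dtype=bool)
    urgent = np.empty(n, dtype=bool)
    for label, mask in (("positive", status), ("negative", ~status)):
        k = int(mask.sum())
        hems[mask] = rng.random(k) < config.hems_prob[label]
        urgent[mask] = rng.random(k) < config.urgent_intervention_prob[label]

    pb = config.provider_behaviour
    prealert = np.zeros(n, dtype=bool)
    if status.any():
        alpha_pos = _calibrate_intercept(
            ages[status], pb.age_slope_sensitivity, pb.target_sensitivity
        )
        p = expit(alpha_pos + pb.age_slope_sensitivity * (ages[status] - 60.0))
        prealert[status] = rng.random(int(status.sum())) < p
    if (~status).any():
        alpha_neg = _calibrate_intercept(
            ages[~status], pb.age_slope_false_positive, 1.0 - pb.target_specificity
        )
        p = expit(alpha_neg + pb.age_slope_false_positive * (ages[~status] - 60.0))
        prealert[~status] = rng.random(int((~status).sum())) < p

    extra = np.where(
        status,
        rng.random(n) < pb.extra_mtc_conveyance_pos,
        rng.random(n) < pb.extra_mtc_conveyance_neg,
    )
    destination = prealert | extra

    # anticoagulant use rises with age; independent of trauma status
    anticoag = rng.random(n) < np.where(ages >= 65, 0.25, 0.05)

    # vectorised per-stratum vitals draws, indexed back per record
    vitals_first: Dict[str, dict] = {}
    vitals_steps: Dict[str, dict] = {}
    stratum_pos: Dict[str, np.ndarray] = {}
    for label, mask in (("positive", status), ("negative", ~status)):
        first, steps = _draw_vitals_arrays(rng, config.vitals_params[label], int(mask.sum()))
        vitals_first[label], vitals_steps[label] = first, steps
        pos_in_stratum = np.full(n, -1)
        pos_in_stratum[mask] = np.arange(int(mask.sum()))
        stratum_pos[label] = pos_in_stratum

    records: List[IncidentRecord] = []
    truth: Dict[str, bool] = {}
    for i in range(n):
        label = "positive" if status[i] else "negative"
        injuries = _draw_injuries(rng, config.injury_params[label], bool(status[i]))
        vitals = _assemble_vitals(
            config.vitals_params[label], vitals_first[label], vitals_steps[label],
            int(stratum_pos[label][i]), bool(gcs_missing[i]), int(n_meas[i]),
        )
        interventions = set()
        if urgent[i]:
            interventions.add(URGENT_INTERVENTIONS[int(rng.integers(len(URGENT_INTERVENTIONS)))])
        if rng.random() < 0.5:
            interventions.add(ROUTINE_INTERVENTIONS[int(rng.integers(len(ROUTINE_INTERVENTIONS)))])
        special = frozenset({"anticoagulant_use"}) if anticoag[i] else frozenset()
        rid = f"R{i:07d}"
        records.append(
            IncidentRecord(
                record_id=rid,
                report_form_id=None if id_missing[i] else f"PRF{i:09d}",
                age_years=float(round(ages[i], 1)),
                sex="female" if female[i] else "male",
                mechanism=str(mech[i]),
                service=str(service[i]),
                vitals=vitals,
                injuries=injuries,
                interventions=frozenset(interventions),
                special_circumstances=special,
                hems_response=bool(hems[i]),
                provider_prealert_mtc=bool(prealert[i]),
                destination_mtc=bool(destination[i]),
            )
        )
        truth[rid] = bool(status[i])
    return ParentCohort(records=records, truth=truth, config=config)
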