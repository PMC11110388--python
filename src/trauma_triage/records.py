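"""Incident records: the unit of analysis for prehospital triage accuracy.

One :class:`IncidentRecord` describes a single ambulance incident: who the
patient is, how they were injured, the serial vital signs recorded on scene,
the injuries later coded on the Abbreviated Injury Scale (AIS), any urgent
interventions received, and the crew's conveyance decision (pre-alerted
transfer to a Major Trauma Centre or not).

Records round-trip losslessly through JSON lines and through a flat CSV in
which the serial signals are serialised as ``;``-delimited lists and injuries
as ``region:severity:open`` triples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ConfigurationError

AIS_REGIONS = ("head", "face", "thorax", "abdomen", "extremities", "external")

MECHANISMS = (
    "cutting_piercing_stabbing",
    "gunshot",
    "fall_gt_1m",
    "fall_lt_1m",
    "rta_motorcycle",
    "rta_motor_vehicle",
    "rta_bicycle",
    "rta_pedestrian",
    "struck_by_object",
    "struck_by_person",
    "other_unknown",
)

#: Mechanisms coded as penetrating trauma; everything else is blunt.
PENETRATING_MECHANISMS = frozenset({"cutting_piercing_stabbing", "gunshot"})

SERVICES = ("LAS", "SWAS", "WMAS", "YAS")


@dataclass(frozen=True)
class Injury:
    """A single AIS-coded injury."""

    region: str
    severity: int
    open_fracture: bool = False

    def __post_init__(self) -> None:
        if self.region not in AIS_REGIONS:
            raise ConfigurationError(f"unknown AIS body region {self.region!r}")
        if not 1 <= int(self.severity) <= 6:
            raise ConfigurationError(
                f"AIS severity must be in 1..6, got {self.severity!r}"
            )


@dataclass(frozen=True)
class VitalsMeasurement:
    """One timestamped set of vital signs.

    Individual signals may be ``None`` when not recorded; the complete-case
    filter decides whether such records survive into the analysis set.
    """

    time_min: float
    sbp: Optional[float] = None
    rr: Optional[float] = None
    spo2: Optional[float] = None
    gcs: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gcs is not None and not 3 <= self.gcs <= 15:
            raise ConfigurationError(f"GCS must be in 3..15, got {self.gcs}")
        if self.spo2 is not None and not 0 <= self.spo2 <= 100:
            raise ConfigurationError(f"SpO2 must be in 0..100, got {self.spo2}")


@dataclass
class IncidentRecord:
    """One prehospital incident."""

    record_id: str
    age_years: float
    sex: str
    mechanism: str
    service: str
    vitals: list[VitalsMeasurement] = field(default_factory=list)
    injuries: list[Injury] = field(default_factory=list)
    interventions: frozenset[str] = frozenset()
    special_circumstances: frozenset[str] = frozenset()
    hems_response: bool = False
    provider_prealert_mtc: bool = False
    destination_mtc: bool = False
    report_form_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ConfigurationError(f"age must be >= 0, got {self.age_years}")
        if self.sex not in ("female", "male"):
            raise ConfigurationError(f"sex must be female/male, got {self.sex!r}")
        if self.mechanism not in MECHANISMS:
            raise ConfigurationError(f"unknown mechanism {self.mechanism!r}")
        self.interventions = frozenset(self.interventions)
        self.special_circumstances = frozenset(self.special_circumstances)

    @property
    def mode(self) -> str:
        """Blunt vs penetrating, derived from the coded mechanism."""
        return "penetrating" if self.mechanism in PENETRATING_MECHANISMS else "blunt"

    def signal_series(self, signal: str) -> list[Optional[float]]:
        """Ordered series for one vital-sign signal (``sbp``/``rr``/``spo2``/``gcs``)."""
        return [getattr(m, signal) for m in self.vitals]


# ---------------------------------------------------------------------------
# Tabular serialisation
# ---------------------------------------------------------------------------

_SIGNALS = ("sbp", "rr", "spo2", "gcs")


def _series_to_str(values: Sequence[Optional[float]]) -> str:
    return ";".join("" if v is None else format(v, "g") for v in values)


def _str_to_series(text: str, integer: bool = False) -> list[Optional[float]]:
    if text == "":
        return []
    out: list[Optional[float]] = []
    for tok in text.split(";"):
        if tok == "":
            out.append(None)
        else:
            out.append(int(float(tok)) if integer else float(tok))
    return out


def records_to_frame(records: Iterable[IncidentRecord]) -> pd.DataFrame:
    """Flatten records into one row per incident."""
    rows = []
    for r in records:
        row = {
            "record_id": r.record_id,
            "report_form_id": r.report_form_id if r.report_form_id else "",
            "age_years": r.age_years,
            "sex": r.sex,
            "mechanism": r.mechanism,
            "mode": r.mode,
            "service": r.service,
            "vitals_time_min": _series_to_str([m.time_min for m in r.vitals]),
            "hems_response": r.hems_response,
            "provider_prealert_mtc": r.provider_prealert_mtc,
            "destination_mtc": r.destination_mtc,
            "interventions": "|".join(sorted(r.interventions)),
            "special_circumstances": "|".join(sorted(r.special_circumstances)),
            "injuries": ";".join(
                f"{i.region}:{i.severity}:{int(i.open_fracture)}" for i in r.injuries
            ),
        }
        for sig in _SIGNALS:
            row[f"{sig}_series"] = _series_to_str(r.signal_series(sig))
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[IncidentRecord]:
    """Inverse of :func:`records_to_frame`."""
    records = []
    for row in frame.itertuples(index=False):
        times = _str_to_series(str(row.vitals_time_min))
        series = {}
        for sig in _SIGNALS:
            vals = _str_to_series(str(getattr(row, f"{sig}_series")), integer=(sig == "gcs"))
            # an all-missing signal serialises to "", shorter than the series
            vals += [None] * (len(times) - len(vals))
            series[sig] = vals
        vitals = [
            VitalsMeasurement(
                time_min=times[k],
                sbp=series["sbp"][k],
                rr=series["rr"][k],
                spo2=series["spo2"][k],
                gcs=series["gcs"][k],
            )
            for k in range(len(times))
        ]
        injuries = []
        inj_text = str(row.injuries)
        if inj_text:
            for tok in inj_text.split(";"):
                region, sev, open_flag = tok.split(":")
                injuries.append(Injury(region, int(sev), bool(int(open_flag))))
        interventions = frozenset(t for t in str(row.interventions).split("|") if t)
        special = frozenset(
            t for t in str(row.special_circumstances).split("|") if t
        )
        records.append(
            IncidentRecord(
                record_id=str(row.record_id),
                report_form_id=str(row.report_form_id) or None,
                age_years=float(row.age_years),
                sex=str(row.sex),
                mechanism=str(row.mechanism),
                service=str(row.service),
                vitals=vitals,
                injuries=injuries,
                interventions=interventions,
                special_circumstances=special,
                hems_response=bool(row.hems_response),
                provider_prealert_mtc=bool(row.provider_prealert_mtc),
                destination_mtc=bool(row.destination_mtc),
            )
        )
    return records


def write_records_csv(records: Iterable[IncidentRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path) -> list[IncidentRecord]:
    frame = pd.read_csv(path, keep_default_na=False, dtype=str)
    frame["age_years"] = frame["age_years"].astype(float)
    for col in ("hems_response", "provider_prealert_mtc", "destination_mtc"):
        frame[col] = frame[col].map({"True": True, "False": False})
    return frame_to_records(frame)


def write_records_jsonl(records: Iterable[IncidentRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            d = asdict(r)
            d["interventions"] = sorted(r.interventions)
            d["special_circumstances"] = sorted(r.special_circumstances)
            fh.write(json.dumps(d, sort_keys=True) + "\n")


def read_records_jsonl(path) -> list[IncidentRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            d = json.loads(line)
            d["vitals"] = [VitalsMeasurement(**m) for m in d["vitals"]]
            d["injuries"] = [Injury(**i) for i in d["injuries"]]
            d["interventions"] = frozenset(d["interventions"])
            d["special_circumstances"] = frozenset(d["special_circumstances"])
            records.append(IncidentRecord(**d))
    return records
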