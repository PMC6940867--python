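"""Delimited-text readers and writers for traces, tracker logs and protocols.

Formats (all UTF-8, comma-delimited, one header line):

* gas-exchange trace:  ``time_s,vo2_lmin,vco2_lmin``
* tracker log:         ``patient_id,device,activity_id,kcal_start,kcal_end``
* cohort table:        ``patient_id,group,age,sex,height_cm,weight_kg,
  resting_vo2_lmin,kinetics_tau_s``

Protocols serialise to YAML/JSON as a list of
``{id, label, category, duration_s, load_w?, speed_kmh?, incline_pct?}``
plus group and rest gaps. Reading validates invariants (monotone
timestamps, kcal_end >= kcal_start, known columns) and reports offending
line numbers; read∘write is the identity on the in-memory structures.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .protocol import Activity, ActivityProtocol, PatientGroup
from .synthetic import GasExchangeTrace, PatientProfile, TrackerLog

__all__ = [
    "write_trace",
    "read_trace",
    "write_tracker_logs",
    "read_tracker_logs",
    "write_cohort",
    "read_cohort",
    "protocol_to_dict",
    "protocol_from_dict",
    "write_protocol",
    "read_protocol",
]

PathLike = Union[str, Path]

TRACE_COLUMNS = ["time_s", "vo2_lmin", "vco2_lmin"]
LOG_COLUMNS = ["patient_id", "device", "activity_id", "kcal_start", "kcal_end"]
COHORT_COLUMNS = [
    "patient_id", "group", "age", "sex", "height_cm", "weight_kg",
    "resting_vo2_lmin", "kinetics_tau_s",
]


def _require_columns(df: pd.DataFrame, required: list[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def write_trace(trace: GasExchangeTrace, path: PathLike) -> None:
    df = pd.DataFrame({
        "time_s": trace.times, "vo2_lmin": trace.vo2, "vco2_lmin": trace.vco2,
    })
    df.to_csv(path, index=False, float_format="%.10g")


def read_trace(path: PathLike, patient_id: str = "") -> GasExchangeTrace:
    """Read a breath-by-breath trace; rejects non-monotone timestamps by line."""
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, path)
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        # +3: 1-based line numbering, header line, and diff offset
        raise ValueError(
            f"{path}: non-increasing or duplicate timestamp at line {int(bad[0]) + 3}"
        )
    pid = patient_id or Path(path).stem
    return GasExchangeTrace(
        patient_id=pid,
        times=t,
        vo2=df["vo2_lmin"].to_numpy(dtype=float),
        vco2=df["vco2_lmin"].to_numpy(dtype=float),
    )


def write_tracker_logs(logs: list[TrackerLog], path: PathLike) -> None:
    rows = [
        {"patient_id": log.patient_id, "device": log.device,
         "activity_id": aid, "kcal_start": start, "kcal_end": end}
        for log in logs
        for aid, start, end in log.rows
    ]
    pd.DataFrame(rows, columns=LOG_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def read_tracker_logs(path: PathLike) -> list[TrackerLog]:
    """Read per-activity cumulative-kcal rows, grouped by (patient, device)."""
    df = pd.read_csv(path)
    _require_columns(df, LOG_COLUMNS, path)
    bad = df.index[df["kcal_end"] < df["kcal_start"]]
    if len(bad):
        raise ValueError(f"{path}: kcal_end < kcal_start at line {int(bad[0]) + 2}")
    logs = []
    for (pid, device), sub in df.groupby(["patient_id", "device"], sort=True):
        rows = tuple(
            (str(r.activity_id), float(r.kcal_start), float(r.kcal_end))
            for r in sub.itertuples()
        )
        logs.append(TrackerLog(patient_id=str(pid), device=str(device), rows=rows))
    return logs


def write_cohort(profiles: list[PatientProfile], path: PathLike) -> None:
    rows = [
        {"patient_id": p.id, "group": p.group.value, "age": p.age, "sex": p.sex,
         "height_cm": p.height_cm, "weight_kg": p.weight_kg,
         "resting_vo2_lmin": p.resting_vo2_lmin, "kinetics_tau_s": p.kinetics_tau_s}
        for p in profiles
    ]
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def read_cohort(path: PathLike) -> list[PatientProfile]:
    df = pd.read_csv(path)
    _require_columns(df, COHORT_COLUMNS, path)
    return [
        PatientProfile(
            id=str(r.patient_id), group=PatientGroup(r.group), age=float(r.age),
            sex=str(r.sex), height_cm=float(r.height_cm), weight_kg=float(r.weight_kg),
            resting_vo2_lmin=float(r.resting_vo2_lmin),
            kinetics_tau_s=float(r.kinetics_tau_s),
        )
        for r in df.itertuples()
    ]


def protocol_to_dict(protocol: ActivityProtocol) -> dict:
    acts = []
    for a in protocol.activities:
        row = {"id": a.id, "label": a.label, "category": a.category.value,
               "duration_s": a.duration_s}
        if a.load_w is not None:
            row["load_w"] = a.load_w
        if a.speed_kmh is not None:
            row["speed_kmh"] = a.speed_kmh
            row["incline_pct"] = a.incline_pct
        acts.append(row)
    return {
        "group": protocol.group.value,
        "activities": acts,
        "rest_gaps_s": [float(g) for g in protocol.rest_gaps_s],
    }


def protocol_from_dict(data: dict) -> ActivityProtocol:
    acts = tuple(
        Activity(
            id=row["id"], label=row.get("label", row["id"]), category=row["category"],
            duration_s=float(row["duration_s"]),
            load_w=row.get("load_w"), speed_kmh=row.get("speed_kmh"),
            incline_pct=row.get("incline_pct"),
        )
        for row in data["activities"]
    )
    return ActivityProtocol(
        group=PatientGroup(data["group"]),
        activities=acts,
        rest_gaps_s=tuple(data.get("rest_gaps_s") or ()),
    )


def write_protocol(protocol: ActivityProtocol, path: PathLike) -> None:
    path = Path(path)
    data = protocol_to_dict(protocol)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def read_protocol(path: PathLike) -> ActivityProtocol:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return protocol_from_dict(data)
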