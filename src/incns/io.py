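"""CSV dialects for observations, outcomes, cohort tables and exclusion logs.

The observation CSV has one row per patient-observation with a fixed column
order; empty cells denote missing values.  Enum-valued columns use the
lower-case tokens of the corresponding enums in :mod:`incns.scales`.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .cohort import COHORT_COLUMNS, CohortRow, PatientTimeline, cohort_to_frame
from .scales import (
    Arousal,
    Awareness,
    BrainstemReflex,
    ChronicHealth,
    NeuroExam,
    PainResponse,
    PatientObservation,
    PhysioPanel,
    Swallow,
    VentilatorBreathing,
    VerbalResponse,
)

PathLike = Union[str, Path]

OBS_COLUMNS = [
    "patient_id", "t_hours", "age_years", "wbc", "temp_axillary", "albumin",
    "arousal", "awareness", "pupillary_reflex", "corneal_reflex", "verbal",
    "strength_left", "strength_right", "pain_response", "swallow", "intubated",
    "resp_rate", "ventilator_breathing", "heart_rate", "sbp", "map", "glucose",
    "sodium", "potassium", "creatinine", "bilirubin", "pao2", "fio2", "aado2",
    "arterial_ph", "hematocrit", "acute_renal_failure", "chronic_health",
    "gcs_eye", "gcs_verbal", "gcs_motor", "four_eye", "four_motor",
    "four_brainstem", "four_respiration",
]

OUTCOME_COLUMNS = [
    "patient_id", "nicu_los_hours", "drug_induced_coma", "died_in_nicu",
    "mrs_3month", "died_by_3month", "lost_to_followup", "etiology",
]


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if hasattr(value, "value"):  # enum
        return str(value.value)
    if isinstance(value, float) and value.is_integer():
        return str(int(value)) if abs(value) < 1e15 else repr(value)
    return str(value)


def observation_record(obs: PatientObservation) -> dict[str, str]:
    e, p = obs.exam, obs.physio
    values = {
        "patient_id": obs.patient_id, "t_hours": obs.t_hours,
        "age_years": obs.age_years, "wbc": p.wbc, "temp_axillary": p.temp_axillary,
        "albumin": p.albumin, "arousal": e.arousal, "awareness": e.awareness,
        "pupillary_reflex": e.pupillary_reflex, "corneal_reflex": e.corneal_reflex,
        "verbal": e.verbal, "strength_left": e.strength_left,
        "strength_right": e.strength_right, "pain_response": e.pain_response,
        "swallow": e.swallow, "intubated": p.intubated, "resp_rate": p.resp_rate,
        "ventilator_breathing": p.ventilator_breathing, "heart_rate": p.heart_rate,
        "sbp": p.sbp, "map": p.map, "glucose": p.glucose, "sodium": p.sodium,
        "potassium": p.potassium, "creatinine": p.creatinine,
        "bilirubin": p.bilirubin, "pao2": p.pao2, "fio2": p.fio2,
        "aado2": p.aado2, "arterial_ph": p.arterial_ph,
        "hematocrit": p.hematocrit, "acute_renal_failure": p.acute_renal_failure,
        "chronic_health": p.chronic_health, "gcs_eye": e.gcs_eye,
        "gcs_verbal": e.gcs_verbal, "gcs_motor": e.gcs_motor,
        "four_eye": e.four_eye, "four_motor": e.four_motor,
        "four_brainstem": e.four_brainstem, "four_respiration": e.four_respiration,
    }
    return {k: _cell(values[k]) for k in OBS_COLUMNS}


def write_observations(timelines_or_obs, path: PathLike) -> None:
    """Write observation rows (from timelines or a flat observation list)."""
    obs: list[PatientObservation] = []
    for item in timelines_or_obs:
        if isinstance(item, PatientTimeline):
            obs.extend(item.observations)
        else:
            obs.append(item)
    df = pd.DataFrame([observation_record(o) for o in obs], columns=OBS_COLUMNS)
    df.to_csv(path, index=False)


def write_outcomes(timelines: Sequence[PatientTimeline], path: PathLike) -> None:
    records = [{
        "patient_id": tl.patient_id,
        "nicu_los_hours": _cell(tl.nicu_los_hours),
        "drug_induced_coma": _cell(tl.drug_induced_coma),
        "died_in_nicu": _cell(tl.died_in_nicu),
        "mrs_3month": tl.mrs_3month,
        "died_by_3month": _cell(tl.died_by_3month),
        "lost_to_followup": _cell(tl.lost_to_followup),
        "etiology": _cell(tl.etiology),
    } for tl in timelines]
    pd.DataFrame(records, columns=OUTCOME_COLUMNS).to_csv(path, index=False)


def _parse_float(cell) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return None
    return float(cell)


def _parse_int(cell) -> Optional[int]:
    v = _parse_float(cell)
    return None if v is None else int(v)


def _parse_bool(cell) -> bool:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return False
    if isinstance(cell, bool):
        return cell
    s = str(cell).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean cell {cell!r}")


def _parse_enum(enum_cls, cell, default=None):
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return default
    return enum_cls(str(cell).strip())


def observation_from_record(rec: dict) -> PatientObservation:
    exam = NeuroExam(
        arousal=_parse_enum(Arousal, rec["arousal"]),
        awareness=_parse_enum(Awareness, rec["awareness"]),
        pupillary_reflex=_parse_enum(BrainstemReflex, rec["pupillary_reflex"]),
        corneal_reflex=_parse_enum(BrainstemReflex, rec["corneal_reflex"]),
        verbal=_parse_enum(VerbalResponse, rec["verbal"]),
        swallow=_parse_enum(Swallow, rec["swallow"]),
        strength_left=_parse_int(rec["strength_left"]),
        strength_right=_parse_int(rec["strength_right"]),
        pain_response=_parse_enum(PainResponse, rec["pain_response"]),
        gcs_eye=_parse_int(rec["gcs_eye"]),
        gcs_verbal=_parse_int(rec["gcs_verbal"]),
        gcs_motor=_parse_int(rec["gcs_motor"]),
        four_eye=_parse_int(rec["four_eye"]),
        four_motor=_parse_int(rec["four_motor"]),
        four_brainstem=_parse_int(rec["four_brainstem"]),
        four_respiration=_parse_int(rec["four_respiration"]),
    )
    physio = PhysioPanel(
        wbc=_parse_float(rec["wbc"]),
        temp_axillary=_parse_float(rec["temp_axillary"]),
        albumin=_parse_float(rec["albumin"]),
        heart_rate=_parse_float(rec["heart_rate"]),
        sbp=_parse_float(rec["sbp"]),
        resp_rate=_parse_float(rec["resp_rate"]),
        glucose=_parse_float(rec["glucose"]),
        sodium=_parse_float(rec["sodium"]),
        potassium=_parse_float(rec["potassium"]),
        creatinine=_parse_float(rec["creatinine"]),
        bilirubin=_parse_float(rec["bilirubin"]),
        intubated=_parse_bool(rec["intubated"]),
        ventilator_breathing=_parse_enum(VentilatorBreathing, rec["ventilator_breathing"],
                                         VentilatorBreathing.NOT_VENTILATED),
        map=_parse_float(rec["map"]),
        pao2=_parse_float(rec["pao2"]),
        fio2=_parse_float(rec["fio2"]),
        aado2=_parse_float(rec["aado2"]),
        arterial_ph=_parse_float(rec["arterial_ph"]),
        hematocrit=_parse_float(rec["hematocrit"]),
        acute_renal_failure=_parse_bool(rec["acute_renal_failure"]),
        chronic_health=_parse_enum(ChronicHealth, rec["chronic_health"],
                                   ChronicHealth.NONE),
    )
    return PatientObservation(
        patient_id=str(rec["patient_id"]),
        t_hours=_parse_float(rec["t_hours"]),
        age_years=_parse_int(rec["age_years"]),
        exam=exam,
        physio=physio,
    )


def read_observations(path: PathLike) -> dict[str, list[PatientObservation]]:
    """Read the observation CSV, grouped by patient, time-sorted."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV missing columns: {sorted(missing)}")
    grouped: dict[str, list[PatientObservation]] = {}
    for rec in df.to_dict("records"):
        obs = observation_from_record(rec)
        grouped.setdefault(obs.patient_id, []).append(obs)
    for obs_list in grouped.values():
        obs_list.sort(key=lambda o: o.t_hours)
    return grouped


def read_timelines(obs_path: PathLike, outcomes_path: PathLike) -> list[PatientTimeline]:
    """Assemble timelines from the observation and outcome CSVs."""
    grouped = read_observations(obs_path)
    out_df = pd.read_csv(outcomes_path, dtype=str, keep_default_na=False)
    timelines = []
    for rec in out_df.to_dict("records"):
        pid = str(rec["patient_id"])
        if pid not in grouped:
            raise ValueError(f"outcomes row for unknown patient {pid!r}")
        etiology = rec.get("etiology") or None
        timelines.append(PatientTimeline(
            patient_id=pid,
            observations=grouped[pid],
            nicu_los_hours=_parse_float(rec["nicu_los_hours"]),
            drug_induced_coma=_parse_bool(rec["drug_induced_coma"]),
            died_in_nicu=_parse_bool(rec["died_in_nicu"]),
            mrs_3month=_parse_int(rec["mrs_3month"]),
            died_by_3month=_parse_bool(rec["died_by_3month"]),
            lost_to_followup=_parse_bool(rec.get("lost_to_followup", "")),
            etiology=etiology,
        ))
    return timelines


def write_cohort(rows: Sequence[CohortRow], path: PathLike) -> None:
    cohort_to_frame(rows).to_csv(path, index=False)


def read_cohort(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df


def write_exclusions(log: Sequence[dict], path: PathLike) -> None:
    """Exclusion log as JSON lines."""
    with open(path, "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")
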