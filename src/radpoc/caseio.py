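"""Case-file I/O: JSON (canonical) and a flat CSV layout.

The CSV layout mirrors spreadsheet-style input: one row per exposure with
the case-level fields (cancer_group, sex, birth_year, diagnosis_year,
smoking_status, smoking_intensity) repeated on every row, and per-exposure
columns year, dose_type, dose_value/dose_mean/dose_sd/dose_gm/dose_gsd/
dose_low/dose_mode/dose_high, duration_hours, radiation_class.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import CaseSpec, ExposureEvent
from .errors import InputError

__all__ = ["load_case", "save_case", "case_from_dict", "case_to_dict"]

_DOSE_FIELDS = {
    "fixed": ("value",),
    "normal": ("mean", "sd"),
    "lognormal": ("gm", "gsd"),
    "uniform": ("low", "high"),
    "triangular": ("low", "mode", "high"),
}


def case_from_dict(d: dict) -> CaseSpec:
    exposures = [
        ExposureEvent(
            year=int(e["year"]),
            dose=dict(e["dose"]),
            duration_hours=e.get("duration_hours"),
            radiation_class=e.get("radiation_class", "lowLET"),
            organ_class=e.get("organ_class", "internal"),
        )
        for e in d.get("exposures", [])
    ]
    return CaseSpec(
        cancer_group=d["cancer_group"],
        sex=d["sex"],
        birth_year=int(d["birth_year"]),
        diagnosis_year=int(d["diagnosis_year"]),
        exposures=exposures,
        smoking=d.get("smoking"),
    )


def case_to_dict(case: CaseSpec) -> dict:
    out = {
        "cancer_group": case.cancer_group,
        "sex": case.sex,
        "birth_year": case.birth_year,
        "diagnosis_year": case.diagnosis_year,
        "exposures": [
            {
                "year": ex.year,
                "dose": dict(ex.dose),
                **({"duration_hours": ex.duration_hours} if ex.duration_hours else {}),
                "radiation_class": ex.radiation_class,
                "organ_class": ex.organ_class,
            }
            for ex in case.exposures
        ],
    }
    if case.smoking is not None:
        out["smoking"] = dict(case.smoking)
    return out


def _case_from_csv(path: Path) -> CaseSpec:
    df = pd.read_csv(path)
    if df.empty:
        raise InputError(f"case CSV {path} is empty")
    head = df.iloc[0]
    exposures = []
    for _, row in df.iterrows():
        dtype = row["dose_type"]
        if dtype not in _DOSE_FIELDS:
            raise InputError(f"unknown dose_type {dtype!r} in {path}")
        dose = {"type": dtype}
        for fieldname in _DOSE_FIELDS[dtype]:
            dose[fieldname] = float(row[f"dose_{fieldname}"])
        duration = row.get("duration_hours")
        exposures.append(
            ExposureEvent(
                year=int(row["year"]),
                dose=dose,
                duration_hours=None if pd.isna(duration) else float(duration),
                radiation_class=row.get("radiation_class", "lowLET"),
            )
        )
    smoking = None
    if "smoking_status" in df.columns and not pd.isna(head.get("smoking_status")):
        smoking = {"status": head["smoking_status"]}
        if "smoking_intensity" in df.columns and not pd.isna(head.get("smoking_intensity")):
            smoking["intensity"] = float(head["smoking_intensity"])
    return CaseSpec(
        cancer_group=head["cancer_group"],
        sex=head["sex"],
        birth_year=int(head["birth_year"]),
        diagnosis_year=int(head["diagnosis_year"]),
        exposures=exposures,
        smoking=smoking,
    )


def load_case(path) -> CaseSpec:
    """Load a case from JSON (canonical) or the flat CSV layout."""
    path = Path(path)
    if path.suffix == ".csv":
        return _case_from_csv(path)
    return case_from_dict(json.loads(path.read_text()))


def save_case(case: CaseSpec, path) -> None:
    path = Path(path)
    path.write_text(json.dumps(case_to_dict(case), indent=2))
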