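"""CSV/JSON boundary for profiles, validation runs and calibration data.

File units mirror the internal convention (time h, concentration ng/mL,
dose ng). Column layouts:

* profiles: subject_id, dose_ng, time_h, conc_ng_per_ml, blq_flag (0/1)
* validation runs: series, level_ng_per_ml, measured_ng_per_ml
* calibration: series, nominal_ng_per_ml, response_ratio
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CalibrationCurve, SubjectProfile, ValidationRun

__all__ = [
    "read_profiles",
    "write_profiles",
    "read_validation_run",
    "write_validation_run",
    "read_calibration_table",
    "curve_to_json",
    "curve_from_json",
]


def write_profiles(profiles: list[SubjectProfile], path) -> None:
    rows = []
    for p in profiles:
        for t, c, b in zip(p.times, p.concentrations, p.blq):
            rows.append((p.subject_id, p.dose, t, c, int(b)))
    pd.DataFrame(
        rows, columns=["subject_id", "dose_ng", "time_h", "conc_ng_per_ml", "blq_flag"]
    ).to_csv(path, index=False)


def read_profiles(path) -> list[SubjectProfile]:
    df = pd.read_csv(path)
    profiles = []
    for sid, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values("time_h")
        doses = sub["dose_ng"].unique()
        if len(doses) != 1:
            raise ValueError(f"subject {sid} has inconsistent dose entries")
        profiles.append(
            SubjectProfile(
                subject_id=str(sid),
                dose=float(doses[0]),
                times=sub["time_h"].to_numpy(float),
                concentrations=sub["conc_ng_per_ml"].to_numpy(float),
                blq=sub["blq_flag"].to_numpy().astype(bool),
            )
        )
    return profiles


def write_validation_run(run: ValidationRun, path) -> None:
    out = run.data.rename(
        columns={"level": "level_ng_per_ml", "measured": "measured_ng_per_ml"}
    )
    out.to_csv(path, index=False)


def read_validation_run(path) -> ValidationRun:
    df = pd.read_csv(path)
    return ValidationRun(
        df.rename(
            columns={"level_ng_per_ml": "level", "measured_ng_per_ml": "measured"}
        )
    )


def read_calibration_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"series", "nominal_ng_per_ml", "response_ratio"}
    if not required <= set(df.columns):
        raise ValueError(f"calibration file needs columns {sorted(required)}")
    return df


def curve_to_json(curve: CalibrationCurve, path) -> None:
    Path(path).write_text(json.dumps(curve.__dict__, indent=2) + "\n")


def curve_from_json(path) -> CalibrationCurve:
    return CalibrationCurve(**json.loads(Path(path).read_text()))
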