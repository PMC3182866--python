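"""CSV / JSON readers and writers for trial series, cohorts and
parameter files.

CSV is the single tabular interchange format (9-significant-digit float
formatting gives exact write/read round trips at that contract); JSON
carries parameters and fit reports.  Angles are degrees wrapped to
(-180, 180], forces newtons, displacements cm.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    ComplianceProfile,
    DRMParams,
    FreeTuning,
    GaussianTuning,
    MCSRMParams,
    SRMParams,
    TrialSeries,
)
from .schedules import Schedule
from .synthetic_data import CohortSeries

_FLOAT_FMT = "%.9g"

COHORT_COLUMNS = [
    "subject_id", "trial", "mode", "orientation_deg",
    "peak_displacement_cm", "clamp_force_n",
]
SERIES_COLUMNS = [
    "trial", "mode", "orientation_deg", "f", "x_net",
    "error", "abs_error", "adaptation_ratio",
]


def write_series(path, series: TrialSeries) -> None:
    series.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_series(path) -> pd.DataFrame:
    df = _read_csv(path, SERIES_COLUMNS)
    return df


def write_cohort(path, cohort: CohortSeries) -> None:
    cohort.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cohort(path, schedule: Schedule) -> CohortSeries:
    df = _read_csv(path, COHORT_COLUMNS)
    n = len(schedule)
    subjects = sorted(df["subject_id"].unique())
    disp = np.full((len(subjects), n), np.nan)
    force = np.full((len(subjects), n), np.nan)
    for row in df.itertuples(index=False):
        s = subjects.index(row.subject_id)
        disp[s, int(row.trial)] = row.peak_displacement_cm
        force[s, int(row.trial)] = row.clamp_force_n
    return CohortSeries(schedule=schedule, displacement=disp, clamp_force=force)


def _read_csv(path, expected: list[str]) -> pd.DataFrame:
    p = Path(path)
    if p.stat().st_size == 0:
        raise ValueError(f"empty input file: {p}")
    df = pd.read_csv(p)
    if list(df.columns) != expected:
        raise ValueError(
            f"unexpected CSV header in {p}: got {list(df.columns)}, expected {expected}"
        )
    if df.isna().all(axis=1).any():
        raise ValueError(f"ragged/blank rows in {p}")
    return df


# ---------------------------------------------------------------------------
# parameter files


def params_to_dict(params, compliance: ComplianceProfile | None = None) -> dict:
    if isinstance(params, SRMParams):
        d = {"model": "SRM", "alpha": params.retention, "beta": params.learning_rate}
    elif isinstance(params, DRMParams):
        d = {
            "model": "DRM",
            "alpha1": params.retention_slow, "beta1": params.learning_slow,
            "alpha2": params.retention_fast, "beta2": params.learning_fast,
        }
    elif isinstance(params, MCSRMParams):
        if isinstance(params.tuning, GaussianTuning):
            d = {"model": "MCSRM4", "alpha": params.retention, "beta": params.learning_rate,
                 "sigma_deg": params.tuning.sigma_deg, "offset": params.tuning.offset}
        else:
            d = {"model": "MCSRM10", "alpha": params.retention, "beta": params.learning_rate,
                 "weights": list(params.tuning.weights)}
    else:
        raise TypeError(f"unsupported params {type(params)!r}")
    if compliance is not None:
        d["compliance"] = {
            "orientations": list(compliance.orientations),
            "k_plus": list(compliance.k_plus),
            "k_minus": list(compliance.k_minus),
            "gain": compliance.gain,
        }
    return d


def params_from_dict(d: dict):
    model = d["model"].upper()
    compliance = None
    if "compliance" in d:
        c = d["compliance"]
        compliance = ComplianceProfile(
            orientations=tuple(c.get("orientations", (0.0, -45.0, -90.0, -135.0, 180.0))),
            k_plus=tuple(c["k_plus"]), k_minus=tuple(c["k_minus"]), gain=c.get("gain", 1.0),
        )
    if model == "SRM":
        return SRMParams(d["alpha"], d["beta"]), compliance
    if model == "DRM":
        return DRMParams(d["alpha1"], d["beta1"], d["alpha2"], d["beta2"]), compliance
    if model == "MCSRM4":
        return MCSRMParams(d["alpha"], d["beta"], GaussianTuning(d["sigma_deg"], d["offset"])), compliance
    if model == "MCSRM10":
        return MCSRMParams(d["alpha"], d["beta"], FreeTuning(tuple(d["weights"]))), compliance
    raise ValueError(f"unknown model {d['model']!r}")


def save_params(path, params, compliance: ComplianceProfile | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(params_to_dict(params, compliance), fh, indent=1, sort_keys=True)


def load_params(path):
    with open(path) as fh:
        return params_from_dict(json.load(fh))


def save_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)!r}")
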