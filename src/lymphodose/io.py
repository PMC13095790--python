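"""Cohort file I/O.

Cohort CSV: one row per patient with at least
``id,modality,sril,ril_grade,pre_rt_alc,bdt_s,n_fractions``; any further
columns are carried as covariates.  ALC histories live in a long-format
companion CSV ``id,day,alc``; blood DVHs as per-patient files
``dvh_<id>.csv`` in the DVH CSV dialect.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bloodsim import DeliverySchedule
from .cohort import ALC_EXCLUSION_THRESHOLD, PatientRecord
from .dvh import read_dvh_csv, write_dvh_csv, DifferentialDVH, cumulative_to_differential, CumulativeDVH
from .errors import ValidationError

__all__ = ["read_cohort", "write_cohort", "config_hash", "json_sanitize"]

REQUIRED_COLUMNS = ("id", "modality", "sril", "ril_grade", "pre_rt_alc",
                    "bdt_s", "n_fractions")


def read_cohort(path, alc_path=None, dvh_dir=None) -> list:
    """Load patient records, reporting invariant violations with row numbers.

    Checked per row: sril/grade consistency (severe lymphopenia iff grade
    >= 3) and the baseline-ALC exclusion criterion (pre-treatment ALC must
    exceed 500/uL).  All offending rows are listed in one error.
    """
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing required columns: {missing}")

    problems = []
    for row_no, row in frame.iterrows():
        if int(row["sril"]) not in (0, 1):
            problems.append(f"row {row_no}: sril must be 0/1")
            continue
        if bool(int(row["sril"])) != (int(row["ril_grade"]) >= 3):
            problems.append(
                f"row {row_no}: sril={int(row['sril'])} inconsistent with "
                f"ril_grade={int(row['ril_grade'])}"
            )
        if not float(row["pre_rt_alc"]) > ALC_EXCLUSION_THRESHOLD:
            problems.append(
                f"row {row_no}: pre_rt_alc={row['pre_rt_alc']} violates the "
                f"> {ALC_EXCLUSION_THRESHOLD}/uL baseline exclusion criterion"
            )
    if problems:
        raise ValidationError("cohort validation failed:\n  " + "\n  ".join(problems))

    alc_by_id = {}
    if alc_path is not None:
        alc = pd.read_csv(alc_path)
        for pid, grp in alc.groupby("id"):
            alc_by_id[str(pid)] = grp[["day", "alc"]].to_numpy(float)

    extra_cols = [c for c in frame.columns if c not in REQUIRED_COLUMNS]
    records = []
    for _, row in frame.iterrows():
        pid = str(row["id"])
        blood_dvh = None
        if dvh_dir is not None:
            dvh_file = Path(dvh_dir) / f"dvh_{pid}.csv"
            if dvh_file.exists():
                dvh = read_dvh_csv(dvh_file)
                if isinstance(dvh, CumulativeDVH):
                    dvh = cumulative_to_differential(dvh)
                blood_dvh = dvh
        records.append(PatientRecord(
            id=pid,
            modality=str(row["modality"]),
            sril=int(row["sril"]),
            ril_grade=int(row["ril_grade"]),
            pre_rt_alc=float(row["pre_rt_alc"]),
            schedule=DeliverySchedule(int(row["n_fractions"]), float(row["bdt_s"])),
            blood_dvh=blood_dvh,
            alc_series=alc_by_id.get(pid),
            covariates={c: row[c] for c in extra_cols},
        ))
    return records


def write_cohort(records: Sequence[PatientRecord], path,
                 alc_path=None, dvh_dir=None) -> None:
    rows = []
    for r in records:
        row = {
            "id": r.id, "modality": r.modality, "sril": r.sril,
            "ril_grade": r.ril_grade, "pre_rt_alc": r.pre_rt_alc,
            "bdt_s": r.schedule.bdt_s if r.schedule else np.nan,
            "n_fractions": r.schedule.n_fractions if r.schedule else np.nan,
        }
        row.update({k: v for k, v in r.covariates.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)

    if alc_path is not None:
        alc_rows = []
        for r in records:
            if r.alc_series is None:
                continue
            for day, alc in r.alc_series:
                alc_rows.append({"id": r.id, "day": day, "alc": alc})
        pd.DataFrame(alc_rows).to_csv(alc_path, index=False)

    if dvh_dir is not None:
        dvh_dir = Path(dvh_dir)
        dvh_dir.mkdir(parents=True, exist_ok=True)
        for r in records:
            if r.blood_dvh is not None:
                write_dvh_csv(dvh_dir / f"dvh_{r.id}.csv", r.blood_dvh)


def json_sanitize(obj):
    """Recursively convert numpy scalars/arrays and dataclass-like objects
    into JSON-serializable structures."""
    if isinstance(obj, dict):
        return {str(k): json_sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [json_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def config_hash(config_dict: dict) -> str:
    """Stable short hash identifying a run configuration."""
    payload = json.dumps(json_sanitize(config_dict), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
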