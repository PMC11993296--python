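"""Dataset readers and writers (NONMEM-style event-record CSV).

Schema: one row per record with columns

    id, time, evid, cmt, amt, dv, tp, donor_relation,
    conditioning_start, conditioning_stop

``evid`` 0 marks observations (``cmt`` PLT with ``dv`` in 1e9/L, or TP with
``tp`` in g/dL), ``evid`` 1 marks dose events (``cmt`` ATG with ``amt`` in mg,
or TRANSFUSION with ``amt`` 1 — the platelet amount delivered per transfusion
is a model parameter, not a recorded quantity).  Static covariates are
repeated on every row of a subject.  Times are decimal days relative to
transplant (day 0).
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd

from .cohort import SubjectDataset
from .model import CovariateSeries, TreatmentRegimen
from .parameters import IndividualParameters
from .simulate import ObservationRecord

__all__ = ["COLUMNS", "read_dataset", "write_dataset", "save_truth", "load_truth"]

COLUMNS = (
    "id",
    "time",
    "evid",
    "cmt",
    "amt",
    "dv",
    "tp",
    "donor_relation",
    "conditioning_start",
    "conditioning_stop",
)


class DatasetError(ValueError):
    """Schema violation; the message names the offending row and column."""


def write_dataset(subjects, path) -> None:
    """Write subjects as a schema-conformant CSV (deterministic column order)."""
    rows = []
    for s in subjects:
        static = {
            "id": s.subject_id,
            "donor_relation": s.regimen.donor_relation,
            "conditioning_start": s.regimen.conditioning_start,
            "conditioning_stop": s.regimen.conditioning_stop,
        }
        for obs in s.observations:
            rows.append(
                {**static, "time": obs.time, "evid": 0, "cmt": "PLT", "dv": obs.platelet}
            )
        if s.covariates is not None:
            for t, v in zip(s.covariates.times, s.covariates.values):
                rows.append({**static, "time": t, "evid": 0, "cmt": "TP", "tp": v})
        for t, dose in s.regimen.atg_doses:
            rows.append({**static, "time": t, "evid": 1, "cmt": "ATG", "amt": dose})
        for t in s.regimen.transfusion_times:
            rows.append(
                {**static, "time": t, "evid": 1, "cmt": "TRANSFUSION", "amt": 1.0}
            )
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    if len(df):
        df = df.sort_values(["id", "time", "evid", "cmt"], kind="stable")
    df.to_csv(path, index=False, float_format="%.12g")


def _require(condition: bool, row: int, column: str, message: str) -> None:
    if not condition:
        raise DatasetError(f"row {row}, column {column!r}: {message}")


def read_dataset(path) -> list[SubjectDataset]:
    """Read a dataset CSV into per-subject records (grouped by id, time-sorted)."""
    df = pd.read_csv(path, dtype={"id": str, "cmt": str, "donor_relation": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required column(s): {', '.join(missing)}")

    for i, row in df.iterrows():
        rownum = i + 2  # 1-based with header
        _require(np.isfinite(row["time"]), rownum, "time", "must be a finite number")
        _require(row["evid"] in (0, 1), rownum, "evid", f"must be 0 or 1, got {row['evid']!r}")
        if row["evid"] == 0:
            _require(
                row["cmt"] in ("PLT", "TP"), rownum, "cmt",
                f"observation rows need cmt PLT or TP, got {row['cmt']!r}",
            )
            if row["cmt"] == "PLT":
                _require(np.isfinite(row["dv"]), rownum, "dv", "observation requires dv")
            else:
                _require(np.isfinite(row["tp"]), rownum, "tp", "TP record requires tp")
        else:
            _require(
                row["cmt"] in ("ATG", "TRANSFUSION"), rownum, "cmt",
                f"event rows need cmt ATG or TRANSFUSION, got {row['cmt']!r}",
            )
            _require(np.isfinite(row["amt"]), rownum, "amt", "event requires amt")

    dup = df.duplicated(subset=["id", "time", "evid", "cmt"], keep=False)
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate (id, time, evid) record(s) kept as-is",
            stacklevel=2,
        )

    subjects = []
    for sid, grp in df.groupby("id", sort=True):
        grp = grp.sort_values(["time", "evid"], kind="stable")
        obs_rows = grp[(grp["evid"] == 0) & (grp["cmt"] == "PLT")]
        tp_rows = grp[(grp["evid"] == 0) & (grp["cmt"] == "TP")]
        atg_rows = grp[(grp["evid"] == 1) & (grp["cmt"] == "ATG")]
        tx_rows = grp[(grp["evid"] == 1) & (grp["cmt"] == "TRANSFUSION")]
        regimen = TreatmentRegimen(
            conditioning_start=float(grp["conditioning_start"].iloc[0]),
            conditioning_stop=float(grp["conditioning_stop"].iloc[0]),
            atg_doses=tuple(zip(atg_rows["time"], atg_rows["amt"])),
            transfusion_times=tuple(tx_rows["time"]),
            donor_relation=str(grp["donor_relation"].iloc[0]),
        )
        covariates = (
            CovariateSeries(tp_rows["time"].to_numpy(), tp_rows["tp"].to_numpy())
            if len(tp_rows)
            else None
        )
        subjects.append(
            SubjectDataset(
                subject_id=str(sid),
                observations=[
                    ObservationRecord(float(t), float(v))
                    for t, v in zip(obs_rows["time"], obs_rows["dv"])
                ],
                regimen=regimen,
                covariates=covariates,
            )
        )
    return subjects


def save_truth(subjects, path) -> None:
    """Store the generating parameters and noise-free labels of a synthetic cohort."""
    out = {}
    for s in subjects:
        entry = {"true_label": s.true_label}
        if s.true_params is not None:
            d = dataclasses.asdict(s.true_params)
            d["residual_error"] = dataclasses.asdict(s.true_params.residual_error)
            entry["true_params"] = d
        out[s.subject_id] = entry
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)
        fh.write("\n")


def load_truth(path) -> dict:
    """Load a truth file; values carry 'true_label' and 'true_params' dicts."""
    with open(path) as fh:
        raw = json.load(fh)
    for entry in raw.values():
        tp = entry.get("true_params")
        if tp is not None:
            from .parameters import ResidualError

            err = tp.pop("residual_error", None)
            if err is not None:
                tp["residual_error"] = ResidualError(**err)
            entry["true_params"] = IndividualParameters(**tp)
    return raw
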