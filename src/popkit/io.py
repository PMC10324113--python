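"""Canonical dataset CSV, config file and report I/O.

The exchange format is a long-format CSV with one row per observation and the
exact ordered header::

    subject_id,group,body_weight_g,dose_ng,time_h,conc_ng_ml,blq_flag

``conc_ng_ml`` is empty for below-LLOQ rows (``blq_flag`` = 1).  Unknown extra
columns are preserved on read but ignored.  Configs are YAML files mirroring
the StudyDesign / truth / SAEMConfig field names.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .popmodel import Observation, PKDataset, PopulationModel, Subject

__all__ = ["PK_COLUMNS", "read_pk_csv", "write_pk_csv", "read_config", "write_config",
           "write_json_report"]

PK_COLUMNS = (
    "subject_id",
    "group",
    "body_weight_g",
    "dose_ng",
    "time_h",
    "conc_ng_ml",
    "blq_flag",
)

REPORT_SCHEMA_VERSION = 1


def write_pk_csv(ds: PKDataset, path: str | Path) -> None:
    """Serialise a dataset to the canonical CSV (lossless round trip)."""
    rows = []
    for s in ds.subjects:
        for o in s.observations:
            rows.append(
                {
                    "subject_id": s.id,
                    "group": s.group,
                    "body_weight_g": s.body_weight if s.body_weight is not None else "",
                    "dose_ng": s.dose,
                    "time_h": o.time,
                    "conc_ng_ml": "" if o.blq else repr(o.conc),
                    "blq_flag": int(o.blq),
                }
            )
    pd.DataFrame(rows, columns=list(PK_COLUMNS)).to_csv(path, index=False)


def read_pk_csv(
    path: str | Path,
    tau: float = 24.0,
    groups: tuple[str, ...] | None = None,
    reference: str | None = None,
    lloq: float | None = None,
) -> PKDataset:
    """Parse the canonical CSV into a PKDataset.

    Raises a schema error naming any missing required column and row-level
    validation errors carrying the (1-based, header-inclusive) line number.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    missing = [c for c in PK_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")

    subjects: dict[str, Subject] = {}
    order: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        sid = str(row["subject_id"])
        try:
            dose = float(row["dose_ng"])
            time = float(row["time_h"])
            blq = bool(int(row["blq_flag"]))
            conc = math.nan if blq else float(row["conc_ng_ml"])
            if dose < 0:
                raise ValueError(f"negative dose {dose}")
            if time < 0:
                raise ValueError(f"negative time {time}")
            bw = row["body_weight_g"]
            bw = None if pd.isna(bw) or bw == "" else float(bw)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"line {line}: {exc}") from exc
        if sid not in subjects:
            subjects[sid] = Subject(id=sid, group=str(row["group"]), dose=dose, body_weight=bw)
            order.append(sid)
        try:
            subjects[sid].observations.append(Observation(time=time, conc=conc, blq=blq))
        except ValueError as exc:
            raise ValidationError(f"line {line}: {exc}") from exc
    return PKDataset(
        subjects=[subjects[s] for s in order],
        tau=tau,
        groups=groups,
        reference=reference,
        lloq=lloq,
    )


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(cfg), fh, sort_keys=False)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _plain(obj):
    """Recursively convert numpy/tuple values to YAML/JSON-safe builtins."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_json_report(payload: dict, path: str | Path) -> None:
    """Write a versioned JSON report."""
    body = {"schema_version": REPORT_SCHEMA_VERSION, **_plain(payload)}
    with open(path, "w") as fh:
        json.dump(body, fh, indent=2)


def model_to_dict(m: PopulationModel, assumptions: dict | None = None) -> dict:
    d = {
        "theta": {"cl_pop": m.theta[0], "v_pop": m.theta[1], "ka_pop": m.theta[2]},
        "beta_log_cl": dict(m.beta),
        "omega": np.asarray(m.omega).tolist(),
        "error_model": m.error_model,
        "error_params": {"a": m.error_params[0], "b": m.error_params[1]},
    }
    if assumptions:
        d["assumption"] = {k: bool(v) for k, v in assumptions.items()}
    return d
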