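"""NONMEM-style rectangular dataset I/O.

Columns: ID, TIME, AMT, RATE, DUR, EVID, MDV, DV, BLQ, then covariates.
Dose rows carry EVID=1, MDV=1 and an empty DV; observation rows carry
EVID=0 with MDV=0 (or MDV=1 when the value is below the limit of
quantification, flagged BLQ=1). A JSON sidecar (<path>.provenance.json)
stores the generating seed/model so synthetic datasets stay reproducible.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Dataset, Observation, SubjectRecord
from .pk import DoseEvent

__all__ = ["write_dataset", "read_dataset", "dataset_to_frame"]

_CORE_COLUMNS = ["ID", "TIME", "AMT", "RATE", "DUR", "EVID", "MDV", "DV", "BLQ"]


def dataset_to_frame(d: Dataset) -> pd.DataFrame:
    rows = []
    for s in d.subjects:
        cov = {k: s.covariates[k] for k in sorted(s.covariates)}
        for dose in s.doses:
            rows.append(
                {
                    "ID": s.id, "TIME": dose.start, "AMT": dose.amount,
                    "RATE": dose.amount / dose.duration, "DUR": dose.duration,
                    "EVID": 1, "MDV": 1, "DV": np.nan, "BLQ": 0, **cov,
                }
            )
        for obs in s.observations:
            rows.append(
                {
                    "ID": s.id, "TIME": obs.time, "AMT": 0.0, "RATE": 0.0,
                    "DUR": 0.0, "EVID": 0, "MDV": int(obs.blq),
                    "DV": obs.conc, "BLQ": int(obs.blq), **cov,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["ID", "TIME", "EVID"], ascending=[True, True, False],
                          kind="stable").reset_index(drop=True)


def write_dataset(d: Dataset, path) -> None:
    path = Path(path)
    dataset_to_frame(d).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    with open(sidecar, "w") as fh:
        json.dump(d.provenance, fh, indent=2, default=float)


def read_dataset(path) -> Dataset:
    """Read a NONMEM-style CSV back into a Dataset (round-trips write_dataset).

    Malformed rows are rejected with their (1-based, header-inclusive) line
    numbers; an empty file yields an empty Dataset with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path} is empty; returning an empty dataset")
        return Dataset(subjects=[])
    if df.empty:
        warnings.warn(f"{path} has no records; returning an empty dataset")
        return Dataset(subjects=[])
    missing = [c for c in _CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")

    cov_cols = [c for c in df.columns if c not in _CORE_COLUMNS]
    problems = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["EVID"] == 1 and not pd.isna(row["DV"]):
            problems.append(f"line {line}: dose row (EVID=1) must not carry a DV")
        if row["EVID"] == 0 and row["MDV"] == 1 and row["BLQ"] != 1:
            problems.append(f"line {line}: DV present but MDV=1 without BLQ flag")
        if row["EVID"] == 0 and pd.isna(row["DV"]):
            problems.append(f"line {line}: observation row lacks a DV")
    if problems:
        raise ValueError(f"{path}: " + "; ".join(problems))

    subjects = []
    for sid, grp in df.groupby("ID", sort=True):
        cov = {c: float(grp.iloc[0][c]) for c in cov_cols}
        doses = [
            DoseEvent(start=float(r.TIME), amount=float(r.AMT), duration=float(r.DUR))
            for r in grp.itertuples()
            if r.EVID == 1
        ]
        obs = [
            Observation(time=float(r.TIME), conc=float(r.DV), blq=bool(r.BLQ))
            for r in grp.itertuples()
            if r.EVID == 0
        ]
        subjects.append(SubjectRecord(id=int(sid), covariates=cov, doses=doses, observations=obs))

    prov = {}
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            prov = json.load(fh)
    return Dataset(subjects=subjects, provenance=prov)
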