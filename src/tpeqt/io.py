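"""Plain-text I/O: waveform records, truth/fiducial/marker tables, series.

Records are written as multi-column CSV (``time_s`` plus one mV column per
lead) with the sampling rate and dialect in ``#``-prefixed header comments.
All tabular outputs are ordinary CSV round-tripped through pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .longitudinal import LongitudinalSeries
from .synthetic import HOSPITAL, SCHOOL, RecordingDialect, WaveformRecord

__all__ = [
    "write_record_csv",
    "read_record_csv",
    "write_table",
    "read_table",
    "read_series_csv",
]


def write_record_csv(record: WaveformRecord, path: str | Path) -> None:
    """Write a record as CSV: header comments, then time_s + per-lead columns."""
    path = Path(path)
    t = np.arange(record.n_samples) / record.fs
    df = pd.DataFrame({"time_s": t})
    for lead in record.leads:
        df[lead] = record.signal(lead)
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs}\n# dialect={record.dialect.name}\n# units={record.units}\n")
        if record.subject_id:
            fh.write(f"# subject_id={record.subject_id}\n")
        df.to_csv(fh, index=False)


def read_record_csv(path: str | Path) -> WaveformRecord:
    """Read a record written by :func:`write_record_csv`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    fs = float(meta.get("fs", 0)) or 1.0 / np.median(np.diff(df["time_s"]))
    dialect = SCHOOL if meta.get("dialect", "school") == "school" else HOSPITAL
    leads = [c for c in df.columns if c != "time_s"]
    return WaveformRecord(
        fs=fs,
        signals={lead: df[lead].to_numpy(dtype=float) for lead in leads},
        dialect=dialect,
        units=meta.get("units", "mV"),
        subject_id=meta.get("subject_id"),
    )


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_series_csv(path: str | Path) -> list[LongitudinalSeries]:
    """Read long-format follow-up series (patient_id, risk_group, months, phase, tpe_qt, qtc)."""
    df = pd.read_csv(path)
    out = []
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("months")
        out.append(
            LongitudinalSeries(
                patient_id=str(pid),
                risk_group=str(grp["risk_group"].iloc[0]),
                months=grp["months"].to_numpy(dtype=float),
                phase=list(grp["phase"]),
                tpe_qt=grp["tpe_qt"].to_numpy(dtype=float),
                qtc=grp["qtc"].to_numpy(dtype=float),
            )
        )
    return out
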