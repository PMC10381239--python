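"""Repolarization markers from fiducials: Tpe, QT, Fridericia QTc, Tpe/QT.

Conventions:

* lead V5 is the representative lead for Tpe, QT and the Tpe/QT ratio;
* QT and QTc use 3 consecutive beats; each beat's Fridericia correction
  ``QT / RR^(1/3)`` uses the *preceding* RR interval (in seconds), and the
  QTc is the mean of the three per-beat corrections;
* Tpe is averaged over the same 3 beats by default (a single-beat mode is
  available);
* the per-lead Tpe spread is summarized as max(V2) - min(V5 or V6);
* intervals are reported to 1 ms, the ratio to 2 decimals (full precision is
  retained internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .errors import InsufficientBeatsError, InvariantError

__all__ = [
    "BeatMarkers",
    "SubjectMarkers",
    "beat_intervals",
    "fridericia_qtc",
    "tpe_qt_ratio",
    "tpe_distribution_width",
    "subject_markers",
    "subject_markers_table",
]

MARKER_COLUMNS = [
    "subject_id",
    "tpe_v5",
    "qt_v5",
    "qtc",
    "tpe_qt",
    "tpe_v1",
    "tpe_v2",
    "tpe_v3",
    "tpe_v4",
    "tpe_v5_lead",
    "tpe_v6",
    "tpe_width",
    "evaluable",
    "reason",
]


@dataclass(frozen=True)
class BeatMarkers:
    """Intervals of one analyzed beat on one lead (ms)."""

    lead: str
    beat_index: int
    tpe: float
    qt: float
    rr_preceding: float

    def __post_init__(self) -> None:
        if not (0 < self.tpe < self.qt):
            raise InvariantError(f"need 0 < tpe < qt, got tpe={self.tpe}, qt={self.qt}")
        if self.rr_preceding <= 0:
            raise InvariantError("rr_preceding must be > 0")


@dataclass
class SubjectMarkers:
    """One subject's representative repolarization markers."""

    subject_id: str | None
    tpe_v5: float = float("nan")
    qt_v5: float = float("nan")
    qtc: float = float("nan")
    tpe_qt_ratio: float = float("nan")
    per_lead_tpe: dict[str, float] = field(default_factory=dict)
    tpe_width: float = float("nan")
    evaluable: bool = True
    reason: str = ""


def beat_intervals(
    fs: float,
    q_onset: int,
    t_peak: int,
    t_end: int,
    rr_preceding: int,
    lead: str = "V5",
    beat_index: int = 0,
) -> BeatMarkers:
    """Convert one beat's fiducial indices into interval markers (ms)."""
    if not (q_onset < t_peak < t_end):
        raise InvariantError("fiducials must satisfy q_onset < t_peak < t_end")
    scale = 1e3 / fs
    return BeatMarkers(
        lead=lead,
        beat_index=beat_index,
        tpe=(t_end - t_peak) * scale,
        qt=(t_end - q_onset) * scale,
        rr_preceding=rr_preceding * scale,
    )


def fridericia_qtc(beats: Sequence[BeatMarkers]) -> float:
    """Fridericia-corrected QT (ms): mean of QT/RR^(1/3) over 3 consecutive beats."""
    if len(beats) != 3:
        raise InsufficientBeatsError(f"Fridericia QTc needs exactly 3 beats, got {len(beats)}")
    idx = [b.beat_index for b in beats]
    if idx != list(range(idx[0], idx[0] + 3)):
        raise InsufficientBeatsError(f"beats must be consecutive, got indices {idx}")
    return float(np.mean([b.qt / (b.rr_preceding / 1e3) ** (1.0 / 3.0) for b in beats]))


def tpe_qt_ratio(tpe_ms: float, qt_ms: float) -> float:
    """Dimensionless Tpe/QT ratio (full precision; round to 2 dp for reporting)."""
    if qt_ms <= 0:
        raise InvariantError("qt must be > 0")
    if not (0 < tpe_ms < qt_ms):
        raise InvariantError(f"need 0 < tpe < qt, got tpe={tpe_ms}, qt={qt_ms}")
    return tpe_ms / qt_ms


def tpe_distribution_width(per_lead_tpe: Mapping[str, Sequence[float] | float]) -> float:
    """Width of the per-lead Tpe spread: max(V2) minus min(V5 or V6), ms.

    Accepts scalars or sequences per lead (subject-level beats or cohort
    pools).  Raises InvariantError when V2 or both of V5/V6 are missing.
    """

    def _vals(key: str) -> list[float]:
        for k, v in per_lead_tpe.items():
            if k.upper() == key:
                arr = np.atleast_1d(np.asarray(v, dtype=float))
                return [float(x) for x in arr[np.isfinite(arr)]]
        return []

    v2 = _vals("V2")
    low = _vals("V5") + _vals("V6")
    if not v2 or not low:
        raise InvariantError("Tpe width needs V2 and at least one of V5/V6")
    return max(v2) - min(low)


def _beats_from_frame(fid: pd.DataFrame, fs: float) -> list[BeatMarkers]:
    """Eligible BeatMarkers for one lead, ordered by beat index."""
    beats = []
    for _, row in fid.sort_values("beat").iterrows():
        if row.get("low_amplitude_excluded") or row.get("negative_t"):
            continue
        if any(pd.isna(row.get(c)) for c in ("q_onset", "t_peak", "t_end", "rr_prev")):
            continue
        beats.append(
            beat_intervals(
                fs,
                int(row["q_onset"]),
                int(row["t_peak"]),
                int(row["t_end"]),
                int(row["rr_prev"]),
                lead=row["lead"],
                beat_index=int(row["beat"]),
            )
        )
    return beats


def _first_consecutive_run(beats: list[BeatMarkers], k: int = 3) -> list[BeatMarkers] | None:
    for i in range(len(beats) - k + 1):
        window = beats[i : i + k]
        if [b.beat_index for b in window] == list(range(window[0].beat_index, window[0].beat_index + k)):
            return window
    return None


def subject_markers(
    fiducials: pd.DataFrame,
    fs: float,
    subject_id: str | None = None,
    single_beat_tpe: bool = False,
) -> SubjectMarkers:
    """Assemble a subject's representative markers from a fiducial table.

    Uses the first run of 3 consecutive artifact-free V5 beats (each with a
    preceding RR) for QT, QTc and — unless ``single_beat_tpe`` — Tpe; the
    per-lead Tpe vector takes the first eligible beat of each lead.  A
    subject whose V5 lead is excluded (low amplitude or negative T) or has
    fewer than 3 eligible consecutive beats is reported as not evaluable.
    """
    out = SubjectMarkers(subject_id=subject_id)
    v5 = fiducials[fiducials["lead"].str.upper() == "V5"]
    if len(v5) and (v5["low_amplitude_excluded"].all() or v5["negative_t"].all()):
        reason = "negative T in V5" if v5["negative_t"].all() else "V5 T amplitude below 0.1 mV"
        out.evaluable, out.reason = False, reason
        return out
    beats = _beats_from_frame(v5, fs)
    run = _first_consecutive_run(beats, 3)
    if run is None:
        raise InsufficientBeatsError(
            f"subject {subject_id}: fewer than 3 eligible consecutive V5 beats"
        )
    out.qt_v5 = float(np.mean([b.qt for b in run]))
    out.tpe_v5 = run[0].tpe if single_beat_tpe else float(np.mean([b.tpe for b in run]))
    out.qtc = fridericia_qtc(run)
    out.tpe_qt_ratio = tpe_qt_ratio(out.tpe_v5, out.qt_v5)

    per_lead: dict[str, float] = {}
    per_lead_all: dict[str, list[float]] = {}
    for lead, grp in fiducials.groupby("lead"):
        lead_beats = _beats_from_frame(grp, fs)
        if lead_beats:
            per_lead[lead] = lead_beats[0].tpe
            per_lead_all[lead] = [b.tpe for b in lead_beats]
    out.per_lead_tpe = per_lead
    try:
        out.tpe_width = tpe_distribution_width(per_lead_all)
    except InvariantError:
        out.tpe_width = float("nan")
    return out


def subject_markers_table(markers: Sequence[SubjectMarkers]) -> pd.DataFrame:
    """Tabulate SubjectMarkers (one row per subject)."""
    rows = []
    for m in markers:
        row = {
            "subject_id": m.subject_id,
            "tpe_v5": m.tpe_v5,
            "qt_v5": m.qt_v5,
            "qtc": m.qtc,
            "tpe_qt": m.tpe_qt_ratio,
            "tpe_width": m.tpe_width,
            "evaluable": m.evaluable,
            "reason": m.reason,
        }
        for lead in ("V1", "V2", "V3", "V4", "V5", "V6"):
            key = "tpe_v5_lead" if lead == "V5" else f"tpe_{lead.lower()}"
            val = next((v for k, v in m.per_lead_tpe.items() if k.upper() == lead), float("nan"))
            row[key] = val
        rows.append(row)
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)
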