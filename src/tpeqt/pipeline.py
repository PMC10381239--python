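"""End-to-end measurement pipeline: records -> fiducials -> subject markers.

This is the closed loop used for validation and reference building: generate
(or load) a cohort of multi-lead records, delineate every lead, extract each
subject's representative markers, and summarize the cohort.
"""

from __future__ import annotations

import pandas as pd

from .delineate import DelineationConfig, delineate_record, fiducials_to_frame
from .errors import InsufficientBeatsError, NoBeatsError
from .markers import SubjectMarkers, subject_markers, subject_markers_table
from .synthetic import CohortResult, CohortSpec, WaveformRecord, sample_cohort

__all__ = ["measure_record", "measure_cohort", "run_reference_pipeline"]


def measure_record(
    record: WaveformRecord,
    config: DelineationConfig | None = None,
    single_beat_tpe: bool = False,
) -> SubjectMarkers:
    """Delineate one record and assemble its subject-level markers.

    Subjects whose V5 lead cannot be measured (excluded lead, too few
    eligible beats, no detectable beats) come back as not evaluable with the
    reason recorded rather than raising, so cohort runs never abort on a
    single bad record.
    """
    sid = record.subject_id
    try:
        fid = fiducials_to_frame(delineate_record(record, config=config), subject_id=sid)
        return subject_markers(fid, record.fs, subject_id=sid, single_beat_tpe=single_beat_tpe)
    except (InsufficientBeatsError, NoBeatsError) as exc:
        return SubjectMarkers(subject_id=sid, evaluable=False, reason=str(exc))


def measure_cohort(
    cohort: CohortResult,
    config: DelineationConfig | None = None,
    single_beat_tpe: bool = False,
) -> pd.DataFrame:
    """Measure every record of a cohort; one marker row per subject."""
    rows = [measure_record(rec, config, single_beat_tpe) for rec in cohort.records]
    table = subject_markers_table(rows)
    return table.merge(cohort.subjects[["subject_id", "stratum"]], on="subject_id", how="left")


def run_reference_pipeline(
    spec: CohortSpec, config: DelineationConfig | None = None
) -> tuple[CohortResult, pd.DataFrame]:
    """Generate a cohort from ``spec`` and measure it; returns (cohort, markers)."""
    cohort = sample_cohort(spec)
    return cohort, measure_cohort(cohort, config)
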