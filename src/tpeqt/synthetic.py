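"""Synthetic ECG generation with analytically known fiducials.

Beats are modelled as sums of Gaussian bumps (P, Q, R, S, T), in the spirit of
the ECGSYN family of generators.  The Gaussian T wave makes the tangent-method
T end analytic: the tangent at the maximal downslope of a positive Gaussian
``A exp(-(t-mu)^2 / 2 sigma^2)`` intersects the isoelectric line exactly at
``mu + 2 sigma``.  Every generated record therefore carries an exact ground
truth for Q onset, R peak, T peak and T end, which downstream delineation can
be validated against.

Two recording dialects are emulated: the school-screening dialect (500 Hz
sampling, 0.5-35 Hz band-pass) and the hospital dialect (150 Hz low-pass).
Filters are zero-phase Butterworth so that filtering does not shift fiducials;
ground truth always refers to the clean, unfiltered waveform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .errors import (
    InsufficientBeatsError,
    NegativeTWaveError,
    ResolutionError,
    SpecificationError,
)

__all__ = [
    "WaveComponent",
    "BeatTemplate",
    "RecordingDialect",
    "SCHOOL",
    "HOSPITAL",
    "WaveformRecord",
    "BeatGroundTruth",
    "StratumDistributions",
    "CohortSpec",
    "CohortResult",
    "GRADE1_DISTRIBUTIONS",
    "GRADE7_DISTRIBUTIONS",
    "reference_cohort_spec",
    "analytic_tangent_tend",
    "analytic_q_onset",
    "beat_template_for",
    "make_beat",
    "make_record",
    "draw_subject_parameters",
    "sample_cohort",
    "apply_dialect_filter",
    "PRECORDIAL_LEADS",
]

#: fraction of the Q-wave amplitude that defines "onset": the Q onset is the
#: time at which the Q component's magnitude first exceeds 5% of its peak.
Q_ONSET_FRACTION = 0.05
#: sigma multiples from the Q center to the 5% crossing: sqrt(2 ln(1/0.05))
_Q_ONSET_K = math.sqrt(2.0 * math.log(1.0 / Q_ONSET_FRACTION))

#: minimum samples per Gaussian sigma for a component to be resolvable
MIN_SAMPLES_PER_SIGMA = 4

PRECORDIAL_LEADS = ("V1", "V2", "V3", "V4", "V5", "V6")


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian bump of a beat.

    Parameters
    ----------
    center : float
        Time offset of the peak within the beat, seconds.
    width : float
        Gaussian sigma, seconds.  For asymmetric waves this is the
        *downslope* (right-hand) sigma.
    amplitude : float
        Signed peak height, mV.
    width_left : float, optional
        Upslope sigma for an asymmetric wave (two half-Gaussians sharing the
        peak).  ``None`` means symmetric.
    """

    center: float
    width: float
    amplitude: float
    width_left: float | None = None

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.width_left is not None and self.width_left <= 0:
            raise ValueError("width_left must be > 0")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the (possibly asymmetric) Gaussian at times ``t`` (s)."""
        x = np.asarray(t, dtype=float) - self.center
        if self.width_left is None:
            return self.amplitude * np.exp(-0.5 * (x / self.width) ** 2)
        sig = np.where(x < 0, self.width_left, self.width)
        return self.amplitude * np.exp(-0.5 * (x / sig) ** 2)


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology of a single beat: optional P/Q/S waves, R and T, beat period.

    ``t2`` is an optional second T lobe; when present the T wave is bifid
    (notched).  The component centers must be strictly increasing in the
    anatomical order P < Q < R < S < T (< T2).
    """

    rr: float
    p: WaveComponent | None = None
    q: WaveComponent | None = None
    r: WaveComponent | None = None
    s: WaveComponent | None = None
    t: WaveComponent | None = None
    t2: WaveComponent | None = None

    def __post_init__(self) -> None:
        if self.rr <= 0:
            raise ValueError("rr must be > 0")
        centers = [c.center for c in self.ordered_components()]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("component centers must be strictly increasing (P<Q<R<S<T)")
        for c in self.ordered_components():
            if not (0 <= c.center < self.rr):
                raise ValueError("component centers must lie within [0, rr)")

    def ordered_components(self) -> list[WaveComponent]:
        return [c for c in (self.p, self.q, self.r, self.s, self.t, self.t2) if c is not None]

    @property
    def t_positive(self) -> bool | None:
        """Sign of the T wave; None when there is no T component."""
        if self.t is None:
            return None
        return self.t.amplitude > 0

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(t, dtype=float))
        for c in self.ordered_components():
            out += c.evaluate(t)
        return out


@dataclass(frozen=True)
class RecordingDialect:
    """Acquisition bandwidth profile of a recording system."""

    name: str
    sampling_rate: float = 500.0
    band: tuple[float, float] | float = (0.5, 35.0)

    def __post_init__(self) -> None:
        if self.name not in ("school", "hospital"):
            raise ValueError("dialect name must be 'school' or 'hospital'")


#: portable school-screening recorder: 500 Hz, 0.5-35 Hz band-pass
SCHOOL = RecordingDialect("school", 500.0, (0.5, 35.0))
#: hospital recorder: 150 Hz low-pass (sampling rate configurable, default 500 Hz)
HOSPITAL = RecordingDialect("hospital", 500.0, 150.0)


def apply_dialect_filter(x: np.ndarray, fs: float, dialect: RecordingDialect) -> np.ndarray:
    """Zero-phase Butterworth filter emulating the recording chain."""
    if dialect.name == "school":
        lo, hi = dialect.band  # type: ignore[misc]
        sos = _sig.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    else:
        sos = _sig.butter(4, float(dialect.band), btype="lowpass", fs=fs, output="sos")  # type: ignore[arg-type]
    return _sig.sosfiltfilt(sos, x)


@dataclass
class WaveformRecord:
    """Sampled multi-lead ECG with acquisition metadata."""

    fs: float
    signals: dict[str, np.ndarray]
    dialect: RecordingDialect
    units: str = "mV"
    subject_id: str | None = None

    @property
    def leads(self) -> list[str]:
        return list(self.signals)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.signals.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def signal(self, lead: str) -> np.ndarray:
        for name, x in self.signals.items():
            if name.upper() == lead.upper():
                return x
        raise KeyError(f"lead {lead!r} not in record (has {self.leads})")


@dataclass(frozen=True)
class BeatGroundTruth:
    """Exact fiducials of one generated beat, relative to beat start.

    Sample indices are ``round(time * fs)``; interval truths are in ms and
    refer to the continuous-time landmarks (not the rounded indices).
    """

    q_onset: int | None
    r_peak: int | None
    t_peak: int | None
    t_end: int | None
    q_onset_s: float | None
    t_peak_s: float | None
    t_end_s: float | None
    tpe_ms: float | None
    qt_ms: float | None
    rr_ms: float


def analytic_tangent_tend(t_component: WaveComponent) -> float:
    """Closed-form tangent-method T end for a Gaussian T wave, in seconds.

    The tangent at the maximal downslope (the inflection at ``mu + sigma``)
    of a positive Gaussian crosses the zero baseline at ``mu + 2 sigma``;
    for an asymmetric T, the downslope-side sigma applies.  Defined only
    for positive T waves.
    """
    if t_component.amplitude <= 0:
        raise NegativeTWaveError(
            "tangent T-end is defined only for the positive T wave"
        )
    return t_component.center + 2.0 * t_component.width


def analytic_q_onset(q_component: WaveComponent) -> float:
    """Time (s) at which the Q wave's magnitude first exceeds 5% of its peak."""
    sigma = q_component.width_left if q_component.width_left is not None else q_component.width
    return q_component.center - _Q_ONSET_K * sigma


def _check_resolution(template: BeatTemplate, fs: float) -> None:
    for c in template.ordered_components():
        sigmas = [c.width] + ([c.width_left] if c.width_left is not None else [])
        for s in sigmas:
            if s * fs < MIN_SAMPLES_PER_SIGMA:
                raise ResolutionError(
                    f"component sigma {s * 1e3:.2f} ms yields {s * fs:.1f} samples per sigma "
                    f"at {fs:.0f} Hz (need >= {MIN_SAMPLES_PER_SIGMA})"
                )


def make_beat(
    template: BeatTemplate, dialect: RecordingDialect = SCHOOL
) -> tuple[np.ndarray, BeatGroundTruth]:
    """Sample one clean beat and derive its exact fiducials.

    The waveform is the sum of the template's Gaussian components over one
    beat period at the dialect's sampling rate; no dialect filter is applied
    here (ground truth refers to the clean waveform).
    """
    fs = dialect.sampling_rate
    _check_resolution(template, fs)
    n = int(round(template.rr * fs))
    t = np.arange(n) / fs
    wave = template.evaluate(t)

    def idx(time_s: float | None) -> int | None:
        return None if time_s is None else int(round(time_s * fs))

    q_on_s = analytic_q_onset(template.q) if template.q is not None else None
    r_s = template.r.center if template.r is not None else None
    t_peak_s = t_end_s = None
    if template.t is not None:
        t_peak_s = template.t.center
        if template.t.amplitude > 0:
            tail = template.t2 if template.t2 is not None else template.t
            t_end_s = analytic_tangent_tend(tail)
    tpe = (t_end_s - t_peak_s) * 1e3 if (t_end_s is not None and t_peak_s is not None) else None
    qt = (t_end_s - q_on_s) * 1e3 if (t_end_s is not None and q_on_s is not None) else None
    truth = BeatGroundTruth(
        q_onset=idx(q_on_s),
        r_peak=idx(r_s),
        t_peak=idx(t_peak_s),
        t_end=idx(t_end_s),
        q_onset_s=q_on_s,
        t_peak_s=t_peak_s,
        t_end_s=t_end_s,
        tpe_ms=tpe,
        qt_ms=qt,
        rr_ms=template.rr * 1e3,
    )
    return wave, truth


# ---------------------------------------------------------------------------
# beat-template construction from interval-level parameters
# ---------------------------------------------------------------------------

#: fixed QRS/P morphology (seconds / mV); Q onset is anchored at 0.16 s so a
#: clean PR segment precedes the QRS and a TP segment follows the T wave.
_Q_ONSET_TIME = 0.16
_Q_SIGMA = 0.008
_Q_AMP = -0.10
_R_SIGMA = 0.010
_S_SIGMA = 0.009
_S_AMP = -0.15
_P_SIGMA = 0.015
_P_AMP = 0.10


def beat_template_for(
    tpe_ms: float,
    qt_ms: float,
    rr_ms: float,
    t_amp: float = 0.30,
    r_amp: float = 1.0,
    bifid: bool = False,
    notch_depth: float = 0.06,
) -> BeatTemplate:
    """Build a beat template whose true Tpe, QT and RR equal the given values.

    The T sigma is ``tpe/2`` (tangent T end at ``mu + 2 sigma``) and the T
    center is placed so that ``T_end - Q_onset = qt``.  A bifid T is realised
    as two offset lobes; its tangent truth then refers to the later lobe.
    """
    if not (0 < tpe_ms < qt_ms):
        raise ValueError("need 0 < tpe < qt")
    if rr_ms <= qt_ms:
        raise ValueError("rr must exceed qt")
    rr = rr_ms / 1e3
    q_center = _Q_ONSET_TIME + _Q_ONSET_K * _Q_SIGMA
    r_center = q_center + 0.025
    s_center = r_center + 0.030
    p_center = _Q_ONSET_TIME - 0.10

    t_sigma = tpe_ms / 2e3
    t_center = _Q_ONSET_TIME + (qt_ms - tpe_ms) / 1e3
    t2 = None
    if bifid:
        # two lobes 3 sigma apart (a clear notch between them); the second
        # lobe carries the tangent truth, so its center+2*sigma must equal
        # the intended T end.
        lobe_sigma = 0.62 * t_sigma
        t_end = t_center + 2 * t_sigma
        t2_center = t_end - 2 * lobe_sigma
        t1_center = t2_center - 3.0 * lobe_sigma
        t = WaveComponent(t1_center, lobe_sigma, t_amp)
        t2 = WaveComponent(t2_center, lobe_sigma, t_amp - notch_depth / 2)
    else:
        t = WaveComponent(t_center, t_sigma, t_amp)
    return BeatTemplate(
        rr=rr,
        p=WaveComponent(p_center, _P_SIGMA, _P_AMP),
        q=WaveComponent(q_center, _Q_SIGMA, _Q_AMP),
        r=WaveComponent(r_center, _R_SIGMA, r_amp),
        s=WaveComponent(s_center, _S_SIGMA, _S_AMP),
        t=t,
        t2=t2,
    )


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


def make_record(
    templates: BeatTemplate | Mapping[str, BeatTemplate],
    n_beats: int = 6,
    noise_sd: float = 0.0,
    wander_amplitude: float = 0.0,
    wander_freq: float = 0.25,
    dialect: RecordingDialect = SCHOOL,
    seed: int | np.random.Generator | None = None,
    subject_id: str | None = None,
    apply_filter: bool = True,
) -> tuple[WaveformRecord, pd.DataFrame]:
    """Concatenate beats into a (possibly multi-lead) record plus truth table.

    Additive white noise and a sinusoidal baseline wander are injected before
    the dialect filter; ground truth refers to the clean waveform.  The truth
    table has one row per (lead, beat) with absolute sample indices.
    """
    if n_beats < 3:
        raise InsufficientBeatsError(
            f"need at least 3 beats for marker analysis, got {n_beats}"
        )
    if not isinstance(templates, Mapping):
        templates = {"V5": templates}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = dialect.sampling_rate

    rr = {lead: tpl.rr for lead, tpl in templates.items()}
    if len(set(rr.values())) != 1:
        raise ValueError("all leads of one record must share the beat period")
    rr0 = next(iter(rr.values()))
    n_total = int(round(n_beats * rr0 * fs))
    t_axis = np.arange(n_total) / fs

    signals: dict[str, np.ndarray] = {}
    rows = []
    for lead, tpl in templates.items():
        _check_resolution(tpl, fs)
        clean = np.zeros(n_total)
        _, truth = make_beat(tpl, dialect)
        for b in range(n_beats):
            offset = b * rr0
            for c in tpl.ordered_components():
                w = max(c.width, c.width_left or 0.0)
                lo = max(0, int((offset + c.center - 8 * w) * fs))
                hi = min(n_total, int((offset + c.center + 8 * w) * fs) + 1)
                clean[lo:hi] += replace(c, center=c.center + offset).evaluate(t_axis[lo:hi])
            off_idx = int(round(offset * fs))
            rows.append(
                {
                    "subject_id": subject_id,
                    "lead": lead,
                    "beat": b,
                    "q_on": None if truth.q_onset is None else truth.q_onset + off_idx,
                    "r_peak": None if truth.r_peak is None else truth.r_peak + off_idx,
                    "t_peak": None if truth.t_peak is None else truth.t_peak + off_idx,
                    "t_end": None if truth.t_end is None else truth.t_end + off_idx,
                    "tpe_ms": truth.tpe_ms,
                    "qt_ms": truth.qt_ms,
                    "rr_ms": truth.rr_ms,
                }
            )
        noisy = clean.copy()
        if wander_amplitude:
            phase = rng.uniform(0, 2 * np.pi)
            noisy = noisy + wander_amplitude * np.sin(2 * np.pi * wander_freq * t_axis + phase)
        if noise_sd:
            noisy = noisy + rng.normal(0.0, noise_sd, size=n_total)
        signals[lead] = apply_dialect_filter(noisy, fs, dialect) if apply_filter else noisy

    record = WaveformRecord(fs=fs, signals=signals, dialect=dialect, subject_id=subject_id)
    return record, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StratumDistributions:
    """Per-stratum normal distributions of the true marker parameters.

    Intervals in ms, T amplitude (lead V5) in mV, each as (mean, sd).
    """

    tpe: tuple[float, float]
    qt: tuple[float, float]
    rr: tuple[float, float]
    t_amp: tuple[float, float] = (0.30, 0.05)

    def __post_init__(self) -> None:
        for name in ("tpe", "qt", "rr", "t_amp"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} SD must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Declarative description of a synthetic cohort.

    ``strata`` maps a stratum label (e.g. sex) to ``(proportion,
    StratumDistributions)``; proportions must sum to 1.
    """

    n_subjects: int
    strata: Mapping[str, tuple[float, StratumDistributions]]
    seed: int
    dialect: RecordingDialect = SCHOOL
    n_beats: int = 6
    noise_sd: float = 0.01
    wander_amplitude: float = 0.05

    def __post_init__(self) -> None:
        total = sum(p for p, _ in self.strata.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("stratum proportions must sum to 1")


@dataclass
class CohortResult:
    """Generated cohort: records, per-(lead,beat) truth table, subject truths."""

    records: list[WaveformRecord]
    truth_table: pd.DataFrame
    subjects: pd.DataFrame


# Per-lead morphology profile across the precordial leads.  V2 carries the
# widest, largest T (it shows the broadest Tpe spread on real tracings) and
# V5/V6 the cleanest, narrowest; V5 is the representative lead so its scale
# is exactly 1.
LEAD_TPE_SCALE = {"V1": 0.95, "V2": 1.20, "V3": 1.10, "V4": 1.05, "V5": 1.00, "V6": 0.97}
LEAD_T_AMP_SCALE = {"V1": 0.55, "V2": 1.50, "V3": 1.30, "V4": 1.15, "V5": 1.00, "V6": 0.85}
LEAD_R_AMP = {"V1": 0.40, "V2": 0.70, "V3": 0.90, "V4": 1.20, "V5": 1.10, "V6": 0.90}

#: feasibility margins enforced by rejection sampling (ms); they keep the
#: QRS-T layout physically well-formed inside the beat.
_MIN_QT_TPE_GAP = 150.0  # qt - 1.3*tpe
_MIN_RR_QT_GAP = 250.0
_MAX_REJECT_TRIES = 400


def _draw_one(dist: StratumDistributions, rng: np.random.Generator) -> dict[str, float]:
    for _ in range(_MAX_REJECT_TRIES):
        tpe = rng.normal(*dist.tpe)
        qt = rng.normal(*dist.qt)
        rr = rng.normal(*dist.rr)
        t_amp = rng.normal(*dist.t_amp)
        if (
            tpe > 0
            and qt > tpe
            and qt - 1.3 * tpe >= _MIN_QT_TPE_GAP
            and rr - qt >= _MIN_RR_QT_GAP
            and t_amp >= 0.12
        ):
            return {"tpe_ms": tpe, "qt_ms": qt, "rr_ms": rr, "t_amp": t_amp}
    raise SpecificationError(
        "parameter distributions are infeasible (rejection rate > 99%)"
    )


def _stratum_counts(spec: CohortSpec) -> dict[str, int]:
    """Largest-remainder allocation of n_subjects across strata."""
    raw = {k: spec.n_subjects * p for k, (p, _) in spec.strata.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = spec.n_subjects - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def draw_subject_parameters(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-subject ground-truth parameters (no waveforms built).

    Rejection sampling (not truncation) enforces positivity, ``tpe < qt`` and
    the layout margins, so the accepted distributions stay interpretable.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for stratum, count in _stratum_counts(spec).items():
        _, dist = spec.strata[stratum]
        for _ in range(count):
            row = _draw_one(dist, rng)
            row.update({"subject_id": f"S{sid:04d}", "stratum": stratum})
            rows.append(row)
            sid += 1
    cols = ["subject_id", "stratum", "tpe_ms", "qt_ms", "rr_ms", "t_amp"]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def subject_templates(params: Mapping[str, float]) -> dict[str, BeatTemplate]:
    """Six precordial-lead templates for one subject's true parameters.

    The subject's true Tpe applies to lead V5; the other leads scale the T
    width and amplitude by the fixed lead profile, with Q onset (hence QT's
    start) shared across leads and the per-lead T end shifting with Tpe.
    """
    out = {}
    for lead in PRECORDIAL_LEADS:
        out[lead] = beat_template_for(
            tpe_ms=params["tpe_ms"] * LEAD_TPE_SCALE[lead],
            qt_ms=params["qt_ms"],
            rr_ms=params["rr_ms"],
            t_amp=params["t_amp"] * LEAD_T_AMP_SCALE[lead],
            r_amp=LEAD_R_AMP[lead],
        )
    return out


def sample_cohort(spec: CohortSpec) -> CohortResult:
    """Generate a seeded cohort of multi-lead records with ground truth.

    Per-subject true Tpe/QT/RR/T-amplitude are drawn from the stratum
    distributions (rejection-sampled for feasibility); each subject gets a
    six-lead record built from :func:`subject_templates` with the spec's
    noise, wander and dialect.  Identical spec + seed gives bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = draw_subject_parameters(spec, rng)
    records: list[WaveformRecord] = []
    truths = []
    for _, row in subjects.iterrows():
        templates = subject_templates(row)
        rec, truth = make_record(
            templates,
            n_beats=spec.n_beats,
            noise_sd=spec.noise_sd,
            wander_amplitude=spec.wander_amplitude,
            dialect=spec.dialect,
            seed=rng,
            subject_id=row["subject_id"],
        )
        records.append(rec)
        truths.append(truth)
    truth_table = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(
            columns=["subject_id", "lead", "beat", "q_on", "r_peak", "t_peak", "t_end", "tpe_ms", "qt_ms", "rr_ms"]
        )
    )
    return CohortResult(records=records, truth_table=truth_table, subjects=subjects)


# ---------------------------------------------------------------------------
# reference-cohort presets (healthy Japanese schoolchildren)
# ---------------------------------------------------------------------------

# Interval distributions of the two school grades (1st grade: 6-7 y, 7th
# grade: 12-13 y).  Mean RR is set so that Fridericia QTc (QT / RR^(1/3))
# matches the grade's mean QTc: rr = (qt_mean / qtc_mean)^3.
GRADE1_DISTRIBUTIONS = StratumDistributions(
    tpe=(70.0, 7.0), qt=(328.0, 22.0), rr=(726.0, 70.0), t_amp=(0.30, 0.05)
)
GRADE7_DISTRIBUTIONS = StratumDistributions(
    tpe=(78.0, 9.0), qt=(364.0, 27.0), rr=(845.0, 80.0), t_amp=(0.30, 0.05)
)

#: male/female proportions observed in the two screened grades
_GRADE_SEX_SPLIT = {1: (0.49, 0.51), 7: (0.56, 0.44)}
_GRADE_DISTS = {1: GRADE1_DISTRIBUTIONS, 7: GRADE7_DISTRIBUTIONS}


def reference_cohort_spec(grade: int, n_subjects: int = 100, seed: int = 0, **kwargs) -> CohortSpec:
    """Cohort spec calibrated to the published 1st- or 7th-grade reference data."""
    if grade not in _GRADE_DISTS:
        raise ValueError("grade must be 1 or 7")
    m, f = _GRADE_SEX_SPLIT[grade]
    dist = _GRADE_DISTS[grade]
    return CohortSpec(
        n_subjects=n_subjects,
        strata={"M": (m, dist), "F": (f, dist)},
        seed=seed,
        **kwargs,
    )
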