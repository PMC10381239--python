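# tpeqt — ventricular repolarization markers from pediatric ECG

`tpeqt` is an analysis pipeline for the ECG markers of ventricular
repolarization dispersion used to monitor arrhythmia risk in children —
in particular childhood-leukemia patients treated with anthracyclines, whose
cardiac complications can surface years after chemotherapy. It covers the
whole measurement chain:

1. **Synthetic ECG generation** (`tpeqt.synthetic`) — multi-lead records
   built from Gaussian wave components, so every fiducial has an analytic
   ground truth; seeded cohorts whose true marker distributions are
   calibrated to published reference values for Japanese 1st graders
   (6–7 y) and 7th graders (12–13 y).
2. **Delineation** (`tpeqt.delineate`) — R peaks, Q onset, T peak, and the
   **tangent-method T end**: the intersection of the isoelectric line with
   the tangent at the maximal downslope of the positive T wave. QC rules:
   leads with T amplitude < 0.1 mV are excluded, negative-T leads are
   excluded, and a T wave is *bifid* when a notch appears in ≥ 4 leads at
   the same timing (bifid T stays in the QT interval).
3. **Markers** (`tpeqt.markers`) — per-lead Tpe (T peak → T end), 3-beat QT
   from lead V5, Fridericia-corrected QTc = mean over 3 consecutive beats of
   QT/RR^1/3 (RR in s), and the representative **Tpe/QT ratio** from V5;
   plus the per-lead Tpe spread max(V2) − min(V5, V6).
4. **Reference limits** (`tpeqt.reference`) — stratified sampling,
   Shapiro–Wilk normality, unpaired Student t comparisons, mean ± SD
   summaries and the **upper reference limit mean + 2·SD** (0.21 ± 0.02 →
   0.25 for the ratio), and Bland–Altman inter-observer agreement.
5. **Longitudinal monitoring** (`tpeqt.longitudinal`) — per-patient Tpe/QT
   and QTc follow-up series, exceedance flagging (ratio > 0.25 strictly;
   QTc ≥ 450 ms), and classification of elevations as never / transient /
   persistent.

## Worked example

```python
from tpeqt.synthetic import reference_cohort_spec
from tpeqt.pipeline import run_reference_pipeline
from tpeqt.reference import summarize

spec = reference_cohort_spec(grade=1, n_subjects=100, seed=1)
cohort, markers = run_reference_pipeline(spec)
ev = markers[markers.evaluable]
s = summarize(ev.tpe_qt, marker="tpe_qt")
print(f"Tpe {ev.tpe_v5.mean():.1f} ms, QT {ev.qt_v5.mean():.1f} ms, "
      f"QTc {ev.qtc.mean():.1f} ms, Tpe/QT {s.mean:.3f}±{s.sd:.3f} "
      f"-> upper limit {s.upper_limit:.3f}")
```

prints

```
Tpe 69.0 ms, QT 328.2 ms, QTc 367.6 ms, Tpe/QT 0.211±0.024 -> upper limit 0.260
```

i.e. a 100-subject cohort generated with true Tpe ~ N(70, 7²) ms,
QT ~ N(328, 22²) ms and RR set so Fridericia QTc averages 365 ms is pushed
through the full automated measurement and recovers those calibrated means
to within sampling error; the mean + 2SD of the measured ratio is the
upper limit used for patient follow-up.

The numbered scripts under `analysis/` run the complete study flow
(`01_simulate_cohorts.py` → `02_measure_markers.py` →
`03_reference_limits.py` → `04_longitudinal_monitoring.py`), writing their
tables under `results/`. The last script builds a 17-patient simulated
treatment cohort in which three high-risk patients show transient
intensive-phase Tpe/QT elevations above 0.25 while every QTc stays below
450 ms.

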