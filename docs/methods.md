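# Methods

## Waveform model and analytic ground truth

Each beat is a sum of Gaussian components for P, Q, R, S and T (the ECGSYN
family of morphology models). This choice makes the tangent definition of
the T-wave end closed-form: for a positive Gaussian T with peak at μ and
width σ, the tangent at the maximal downslope (the inflection at μ + σ)
crosses the isoelectric line exactly at **μ + 2σ**. An asymmetric T is two
half-Gaussians sharing the peak, and the tangent truth uses the
downslope-side σ. A bifid (notched) T is two lobes 3 lobe-σ apart; the
tangent truth then belongs to the later lobe. The true Q onset is the time
at which the Q component's magnitude first exceeds 5% of its peak, i.e.
μ_Q − σ_Q·√(2 ln 20); this operational definition is a package choice, since
"start of the Q wave" has no universal analytic definition.

Beat templates are parameterized directly by the target intervals: T width
σ = Tpe/2, and the T center placed so that T end − Q onset equals the target
QT. A fixed QRS/P geometry (Q σ = 8 ms, R σ = 10 ms, S σ = 9 ms, P σ = 15 ms,
Q onset anchored 160 ms into the beat) leaves clean PR and TP segments for
baseline estimation. Records are built by concatenating beats at a constant
RR; a component σ with fewer than 4 samples is rejected as unresolvable.

Two acquisition dialects are emulated with zero-phase Butterworth filters
(so filtering shifts no fiducial symmetrically): the *school* screening
recorder (500 Hz sampling, 0.5–35 Hz band-pass, 2nd order) and the
*hospital* recorder (150 Hz low-pass, 4th order). White noise (default SD
0.01 mV for cohorts) and a 0.25 Hz sinusoidal baseline wander (default
0.05 mV) are injected **before** the filter; ground truth always refers to
the clean waveform.

## Cohort calibration

Per-subject true Tpe, QT, RR and V5 T amplitude are drawn independently
from per-stratum normal distributions, with rejection sampling (not
truncation, so the accepted distributions remain interpretable) enforcing
positivity, Tpe < QT, and layout feasibility margins (QT − 1.3·Tpe ≥ 150 ms,
RR − QT ≥ 250 ms); these margins reject well under 1% of draws at the
reference calibrations. The presets are calibrated to the published
reference values for healthy Japanese schoolchildren:

| grade | Tpe (ms) | QT (ms) | QTc (ms) | sex split |
|---|---|---|---|---|
| 1st (6–7 y) | 70 ± 7 | 328 ± 22 | 365 | 49 M / 51 F |
| 7th (12–13 y) | 78 ± 9 | 364 ± 27 | 385 | 56 M / 44 F |

No heart rate is published, so mean RR is derived from the Fridericia
identity, RR = (QT_mean/QTc_mean)³ — 726 ms (grade 1) and 845 ms (grade 7) —
with SDs of 70/80 ms chosen as physiologically plausible for these ages.
T amplitude is N(0.30, 0.05²) mV in V5. Because Tpe and QT are drawn
independently, the induced cohort mean of Tpe/QT is E[Tpe]/E[QT]·(1+cv²_QT)
≈ 0.213 (grade 1) / 0.216 (grade 7), which rounds to the published 0.21 /
0.22; the published per-subject ratios would additionally reflect whatever
Tpe–QT correlation real children have, which is not modeled.

The six precordial leads share Q onset and T end but scale the T width and
amplitude by a fixed lead profile in which V2 carries the widest and tallest
T and V5/V6 the narrowest — mirroring the observation that V2 readings show
the largest Tpe spread — so the spread statistic max(V2) − min(V5, V6) is
strictly positive by construction.

## Delineation

All windows a human reader resolves by eye are explicit configuration with
these defaults: derivative smoothing 10 ms, tangent fit window 10 ms,
baseline = median of the PR segment 95–55 ms before the R peak, T search
from R+120 ms to 220 ms before the next R, notch prominence 0.02 mV, bifid
agreement tolerance 20 ms across ≥ 4 leads, T-amplitude exclusion threshold
0.1 mV with a strict `<` at the boundary, Q-onset fraction 5%.

* **R peaks** are detected on the rectified smoothed slope (the QRS is far
  steeper than even a tall T wave) with a 0.3 s refractory period, then
  refined to the local signal maximum.
* **T end** fits a least-squares line to the lightly smoothed signal over
  10 ms centred at the maximal downslope and intersects it with the
  baseline. Two numerical choices matter and were set by measuring
  fiducial error against generator truth: the downslope argmin uses a
  wider (20 ms) smoothing window than the fit, and the line is fitted to
  the smoothed rather than raw samples — with matched windows the argmin
  of a noisy derivative systematically selects spuriously steep slopes and
  biases the intersection ~1 ms early.
* **Q onset** finds the sub-sample 5%-of-Q-amplitude crossing scanning
  backward from the Q trough, then applies a *dialect self-calibration*:
  the acquisition low-pass widens the narrow Q wave and drags the crossing
  several ms early, so the detector measures its own offset once per
  (dialect, sampling rate, config) on a noiseless reference beat passed
  through the same chain, and subtracts it. Without this correction QT is
  overestimated by ≈ 4 ms under the school dialect.
* **Ties** at equal T maxima break to the earliest index; negative-T leads
  are flagged and excluded rather than mirrored (the tangent method is
  defined for the positive T wave only); a beat with no resolvable Q falls
  back to a derivative-threshold QRS onset and is flagged.

The zero-phase filters leave edge transients on the first and last beats of
a record; the marker layer only ever uses interior beats (the first run of
3 consecutive eligible beats with a preceding RR, which in a 6-beat record
is beats 1–3).

## Markers

QT and QTc use 3 consecutive V5 beats; each beat's Fridericia correction
QT/RR^(1/3) takes the **preceding** RR (standard convention). Tpe is
averaged over the same 3 beats for internal consistency (a single-beat mode
exists). The Tpe/QT ratio divides the two 3-beat means. Intervals are
reported to 1 ms and the ratio to 2 decimals; full precision is kept
internally. A subject whose V5 T is low-amplitude or negative, or who lacks
3 eligible consecutive beats, is reported not-evaluable with the reason.

## Reference statistics and monitoring

The upper reference limit is mean + 2·SD exactly (not 1.96·SD): 0.21 + 2·0.02
= 0.25 for the ratio. Group comparison is the equal-variance Student t-test
(Welch behind a flag); non-normal strata are still summarized as mean ± SD
with the Shapiro–Wilk p recorded. The inter-observer analysis reports
Bland–Altman bias and 1.96·SD limits plus Pearson r — the original
evaluation's statistic is not specified anywhere, so this choice is labeled
as the package's own.

Follow-up flagging uses strict `>` at the ratio limit (0.25 itself is
normal) and `≥` at the 450 ms QTc bound (normal is defined as < 450 ms). An
elevation is *transient* when the last exceedance is followed by at least 2
sub-threshold measurements, *persistent* otherwise; a persistent call with
fewer than 2 post-exceedance measurements is flagged low-confidence. The
0.25 default corresponds to the pooled/either-grade limit (both grades round
to 0.25); the threshold is configurable.

## Problem sizes and validation scope

Validation runs use 100-subject cohorts with 6 beats per record (the sizes
of the reference study groups), 1000 draws for distribution-calibration
checks, and 100 seeded repetitions for test-power properties. On these
cohorts the full pipeline recovers the calibrated means of Tpe, QT, QTc and
Tpe/QT within 3 standard errors, and on noiseless records every fiducial
matches the analytic truth within 2 samples.

## Limitations

The generator reproduces interval structure, not physiology: no heart-rate
variability or respiration coupling, constant RR within a record, no
Tpe–QT correlation, no ectopy or artifact beats, and a fixed QRS geometry.
Passing tests therefore demonstrate the correctness of the measurement
chain under known morphology, not delineation performance on pathological
real-world tracings (biphasic T, U waves, fusion, muscle artifact). The
Q-onset self-calibration assumes a Q width near the nominal 8 ms; strongly
different QRS morphologies retain a residual bandwidth bias of a few ms.
The longitudinal patient simulator is a fixture mirroring reported
trajectory patterns, not a pharmacokinetic or dose–response model.
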