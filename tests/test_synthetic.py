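"""Generator tests: analytic tangent oracle, truth consistency, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tpeqt.errors import (
    InsufficientBeatsError,
    NegativeTWaveError,
    ResolutionError,
    SpecificationError,
)
from tpeqt.synthetic import (
    SCHOOL,
    BeatTemplate,
    CohortSpec,
    StratumDistributions,
    WaveComponent,
    analytic_tangent_tend,
    beat_template_for,
    draw_subject_parameters,
    make_beat,
    make_record,
    reference_cohort_spec,
    sample_cohort,
)


def numeric_tangent_tend(component: WaveComponent, dt: float = 1e-5) -> float:
    """Independent numeric oracle: sample the bump finely, find the maximal
    downslope, draw the tangent there, intersect the zero baseline."""
    t = np.arange(component.center - 6 * component.width, component.center + 6 * component.width, dt)
    y = component.evaluate(t)
    dy = np.gradient(y, dt)
    i = int(np.argmin(dy))
    return t[i] - y[i] / dy[i]


class TestAnalyticTangent:
    @pytest.mark.parametrize(
        "center,width,amp",
        [(0.30, 0.05, 0.3), (0.30, 0.035, 0.15), (0.45, 0.02, 0.6), (0.25, 0.06, 0.45)],
    )
    def test_matches_numeric_oracle(self, center, width, amp):
        comp = WaveComponent(center, width, amp)
        analytic = analytic_tangent_tend(comp)
        assert analytic == pytest.approx(center + 2 * width, abs=1e-12)
        assert analytic == pytest.approx(numeric_tangent_tend(comp), abs=1e-3)

    def test_asymmetric_t_uses_downslope_sigma(self):
        comp = WaveComponent(0.30, 0.05, 0.3, width_left=0.025)
        assert analytic_tangent_tend(comp) == pytest.approx(0.40)
        assert numeric_tangent_tend(comp) == pytest.approx(0.40, abs=1e-3)

    def test_degenerate_width_limit(self):
        # as the T narrows the tangent end collapses onto the peak
        ends = [analytic_tangent_tend(WaveComponent(0.30, w, 0.3)) for w in (1e-3, 1e-5, 1e-7)]
        assert ends == sorted(ends, reverse=True)
        assert ends[-1] == pytest.approx(0.30, abs=1e-6)

    def test_negative_amplitude_errors(self):
        with pytest.raises(NegativeTWaveError):
            analytic_tangent_tend(WaveComponent(0.30, 0.05, -0.3))

    @settings(deadline=None, max_examples=25)
    @given(
        center=st.floats(0.2, 0.5),
        width=st.floats(0.015, 0.08),
        amp=st.floats(0.05, 1.0),
    )
    def test_tangent_closed_form_property(self, center, width, amp):
        comp = WaveComponent(center, width, amp)
        assert analytic_tangent_tend(comp) == pytest.approx(numeric_tangent_tend(comp), abs=2e-3)


class TestMakeBeat:
    def test_truth_t_end_index(self):
        tpl = BeatTemplate(rr=0.8, t=WaveComponent(0.30, 0.05, 0.3))
        wave, truth = make_beat(tpl, SCHOOL)
        assert truth.t_end == round(0.40 * 500) == 200
        assert truth.t_peak == 150
        assert len(wave) == round(0.8 * 500)

    def test_empty_template_is_flat_with_no_fiducials(self):
        wave, truth = make_beat(BeatTemplate(rr=0.8), SCHOOL)
        assert np.all(wave == 0)
        assert truth.q_onset is None and truth.t_peak is None and truth.t_end is None

    def test_unresolvable_sigma_raises(self):
        tpl = BeatTemplate(rr=0.8, t=WaveComponent(0.30, 0.001, 0.3))
        with pytest.raises(ResolutionError):
            make_beat(tpl, SCHOOL)

    def test_interval_truths_match_construction(self):
        tpl = beat_template_for(70.0, 328.0, 726.0)
        _, truth = make_beat(tpl, SCHOOL)
        assert truth.tpe_ms == pytest.approx(70.0, abs=1e-9)
        assert truth.qt_ms == pytest.approx(328.0, abs=1e-9)


class TestMakeRecord:
    def test_same_seed_is_bit_identical(self):
        tpl = beat_template_for(70.0, 328.0, 726.0)
        r1, t1 = make_record(tpl, n_beats=4, noise_sd=0.02, wander_amplitude=0.05, seed=11)
        r2, t2 = make_record(tpl, n_beats=4, noise_sd=0.02, wander_amplitude=0.05, seed=11)
        assert np.array_equal(r1.signal("V5"), r2.signal("V5"))
        assert t1.equals(t2)

    def test_too_few_beats_raises(self):
        tpl = beat_template_for(70.0, 328.0, 726.0)
        with pytest.raises(InsufficientBeatsError):
            make_record(tpl, n_beats=2)

    def test_truth_ordering_invariant(self, noiseless_cohort):
        tt = noiseless_cohort.truth_table
        assert (tt.t_end > tt.t_peak).all()
        assert (tt.t_peak > tt.r_peak).all()
        assert (tt.r_peak > tt.q_on).all()


class TestCohortSampling:
    def test_determinism(self):
        spec = reference_cohort_spec(1, n_subjects=5, seed=3)
        a, b = sample_cohort(spec), sample_cohort(spec)
        assert a.subjects.equals(b.subjects)
        assert all(
            np.array_equal(ra.signal(l), rb.signal(l))
            for ra, rb in zip(a.records, b.records)
            for l in ra.leads
        )

    def test_empty_cohort(self):
        spec = reference_cohort_spec(1, n_subjects=0, seed=3)
        res = sample_cohort(spec)
        assert res.records == [] and len(res.truth_table) == 0 and len(res.subjects) == 0

    def test_calibration_within_three_standard_errors(self):
        # 1000 truth draws recover the specified mean and SD
        spec = reference_cohort_spec(1, n_subjects=1000, seed=17)
        df = draw_subject_parameters(spec)
        for col, (mean, sd) in [("tpe_ms", (70, 7)), ("qt_ms", (328, 22)), ("rr_ms", (726, 70))]:
            n = len(df)
            assert df[col].mean() == pytest.approx(mean, abs=3 * sd / np.sqrt(n))
            assert df[col].std() == pytest.approx(sd, abs=3 * sd / np.sqrt(2 * n))
        assert (df.tpe_ms < df.qt_ms).all()
        assert (df[["tpe_ms", "qt_ms", "rr_ms", "t_amp"]] > 0).all().all()

    def test_infeasible_distributions_raise(self):
        bad = StratumDistributions(tpe=(400.0, 1.0), qt=(300.0, 1.0), rr=(800.0, 1.0))
        spec = CohortSpec(n_subjects=3, strata={"all": (1.0, bad)}, seed=0)
        with pytest.raises(SpecificationError):
            draw_subject_parameters(spec)

    def test_stratum_proportions(self):
        spec = reference_cohort_spec(1, n_subjects=100, seed=2)
        df = draw_subject_parameters(spec)
        counts = df.stratum.value_counts()
        assert counts["M"] == 49 and counts["F"] == 51
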