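import numpy as np
import pytest

from tpeqt.synthetic import (
    SCHOOL,
    beat_template_for,
    make_record,
    reference_cohort_spec,
    sample_cohort,
)


@pytest.fixture(scope="session")
def clean_record():
    """Noiseless, unfiltered single-lead record with its truth table."""
    tpl = beat_template_for(70.0, 328.0, 726.0)
    rec, truth = make_record(
        {"V5": tpl}, n_beats=5, dialect=SCHOOL, apply_filter=False, seed=0, subject_id="S0"
    )
    return rec, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Noiseless (but dialect-filtered) 20-subject reference cohort."""
    spec = reference_cohort_spec(1, n_subjects=20, seed=5, noise_sd=0.0, wander_amplitude=0.0)
    return sample_cohort(spec)
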