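"""Exception hierarchy for the tpeqt pipeline."""


class TpeqtError(Exception):
    """Base class for all tpeqt errors."""


class ResolutionError(TpeqtError):
    """Sampling rate too low to resolve a waveform component (< 4 samples per sigma)."""


class InsufficientBeatsError(TpeqtError):
    """Fewer beats than the marker layer requires (3 consecutive beats)."""


class NoBeatsError(TpeqtError):
    """No R peaks found above the adaptive detection threshold."""


class FiducialError(TpeqtError):
    """A fiducial landmark could not be located (empty window, no downslope, ...)."""


class BaselineError(TpeqtError):
    """The isoelectric baseline segment does not fit inside the record."""


class NegativeTWaveError(TpeqtError):
    """Tangent T-end requested for a non-positive T wave."""


class SpecificationError(TpeqtError):
    """A cohort specification is infeasible (rejection rate too high, bad proportions)."""


class SamplingError(TpeqtError):
    """Stratified sampling request exceeds availability."""


class InvariantError(TpeqtError):
    """A marker invariant is violated (e.g. t_end <= t_peak, qt <= 0)."""
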