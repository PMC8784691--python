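"""Exception hierarchy shared across the package."""


class RVBiomechError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RVBiomechError, ValueError):
    """An input object violates one of its invariants; names the field."""


class InsufficientBeatsError(RVBiomechError):
    """Too few cardiac cycles for the requested summary."""


class DegenerateSignalError(RVBiomechError):
    """A waveform feature (peak, second-derivative maximum) is undefined."""


class NonpositivePressureError(RVBiomechError):
    """The log-linear relaxation fit saw a pressure <= 0."""


class NondecayingSegmentError(RVBiomechError):
    """The diastolic segment does not decay; tau is undefined."""


class InvertedElementError(RVBiomechError):
    """det F <= 0: the marker quadrilateral is inverted or degenerate."""


class FitConvergenceError(RVBiomechError):
    """Non-linear least squares failed from every starting point."""
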