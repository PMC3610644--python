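"""Exception hierarchy for cwesr.

Everything raised deliberately by this package derives from :class:`CwEsrError`
so callers can catch one type at pipeline boundaries.
"""


class CwEsrError(Exception):
    """Base class for all cwesr errors."""


class SpectrumIOError(CwEsrError):
    """A spectrum file is missing, malformed, or violates an invariant."""


class InvalidSpectrumError(CwEsrError):
    """A Spectrum object violates its construction invariants."""


class AxisTooNarrowError(CwEsrError):
    """The requested field axis does not span the simulated lineshape."""


class AlignmentError(CwEsrError):
    """Spectra cannot be brought onto a common field grid."""


class UnresolvedLinesError(CwEsrError):
    """A spectrum does not contain the expected resolved line structure."""


class DegenerateSpectrumError(CwEsrError):
    """An ordered-spectrum measurement was attempted on a spectrum without
    distinct inner/outer hyperfine structure."""


class DecompositionError(CwEsrError):
    """Spectral unmixing or subtraction failed (collinear bases, empty
    remainder, invalid fractions)."""
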