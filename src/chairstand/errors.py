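"""Exception hierarchy shared across the pipeline.

All pipeline errors derive from :class:`ChairstandError` so callers (and the
CLI exit-code mapping) can distinguish bad input from degenerate signals.
"""


class ChairstandError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ChairstandError, ValueError):
    """A file or record does not conform to the documented schema."""


class DataError(ChairstandError, ValueError):
    """Input data is schematically valid but unusable (too short, unordered...)."""


class DegenerateSpectrumError(DataError):
    """The power spectrum carries no dominant peak in the search band."""
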