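"""Exception hierarchy.

Everything the package raises deliberately derives from :class:`SpanError`
so the CLI can catch one type, print the message and exit non-zero.
"""


class SpanError(Exception):
    """Base class for all errors raised by spanpeaks."""


class FormatError(SpanError):
    """A file does not conform to its declared format; message names the line."""


class ModelError(SpanError):
    """Invalid model state or a numerical failure during fitting/decoding."""


class SimulationError(SpanError):
    """Infeasible simulation request (packing, label placement)."""
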