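"""Exception hierarchy.

All library errors derive from :class:`MotifregError` so callers (and the
CLI) can catch one base class and map it to a diagnostic.
"""


class MotifregError(Exception):
    """Base class for all motifreg errors."""


class FormatError(MotifregError):
    """A file does not conform to the expected text dialect."""


class ValidationError(MotifregError):
    """Data violates a structural invariant (labels, signs, shapes)."""


class AlignmentError(MotifregError):
    """Gene / experiment identifier sets cannot be reconciled."""


class ParameterError(MotifregError):
    """A parameter is outside its admissible range."""


class SingularSystemError(MotifregError):
    """A linear system is singular; an unregularised solve cannot proceed."""
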