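"""Exception hierarchy.

All user-facing failures derive from :class:`RingSurveyError`; the CLI maps
them to exit code 2 (validation error) versus 1 (unexpected crash).
"""


class RingSurveyError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RingSurveyError):
    """A file does not conform to its declared format."""


class ValidationError(RingSurveyError):
    """Inputs violate a documented invariant or precondition."""
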