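"""Exception hierarchy for coexkit.

All user-facing failures derive from :class:`CoexkitError` so the CLI can
distinguish validation problems (exit 1) from programming errors.
"""


class CoexkitError(Exception):
    """Base class for all coexkit errors."""


class ParseError(CoexkitError):
    """A file could not be parsed (malformed cell, empty file, short line)."""


class ValidationError(CoexkitError):
    """An input violated a documented invariant or precondition."""


class EmptyResultError(ValidationError):
    """A filter or selection removed everything; an empty result is not usable."""
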