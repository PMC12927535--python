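"""Typed exceptions raised across the package.

All readers and metric functions reject malformed input with one of these,
never with a bare ``ValueError`` from deep inside a dependency.
"""


class LiftQCError(Exception):
    """Base class for all liftqc errors."""


class ValidationError(LiftQCError, ValueError):
    """Input values violate a documented precondition or invariant."""


class FormatError(LiftQCError, ValueError):
    """A file parses but does not have the expected structure or dtype."""


class NoTransferError(LiftQCError):
    """A print produced no main droplets; quantities conditioned on
    droplets being present are undefined.  Callers that build window maps
    catch this and record the distinct ``no_transfer`` state instead of a
    score of zero."""
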