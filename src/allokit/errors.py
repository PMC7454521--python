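"""Exception hierarchy.

All user-facing errors derive from :class:`AllokitError` so callers can
catch package failures with one except clause; the three subclasses
distinguish bad inputs, optimizer failures and malformed tables.
"""


class AllokitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(AllokitError, ValueError):
    """An argument violates a documented precondition."""


class FitFailureError(AllokitError, RuntimeError):
    """A nonlinear fit failed to converge after all restarts."""


class SchemaError(AllokitError, ValueError):
    """A tabular input does not match its declared schema."""
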