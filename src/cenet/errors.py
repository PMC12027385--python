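"""Exception hierarchy for the cenet package.

All cenet-raised errors derive from :class:`CenetError` so callers can
catch package failures with a single except clause; the CLI maps them to
exit code 2.
"""


class CenetError(Exception):
    """Base class for all cenet errors."""


class FormatError(CenetError, ValueError):
    """A tabular input violates its column or value contract.

    Messages name the offending column or carry the 1-based line number
    of the bad row.
    """


class ValidationError(CenetError, ValueError):
    """A record violates a domain invariant (e.g. direction vs means)."""


class UsageError(CenetError, ValueError):
    """Arguments are inconsistent with each other (wrong compartment,
    stage mismatch, unknown export format, ...)."""


class DomainError(CenetError, ValueError):
    """A numeric argument is outside its mathematical domain."""
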