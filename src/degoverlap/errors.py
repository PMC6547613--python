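"""Exception hierarchy.

All package errors derive from :class:`DegOverlapError` so callers can catch
one base class. Validation-type errors (bad arguments, bad configs) are kept
distinct from runtime failures so the CLI can map them to exit codes.
"""


class DegOverlapError(Exception):
    """Base class for all errors raised by this package."""


class InvalidArgumentError(DegOverlapError, ValueError):
    """An argument violates a documented precondition."""


class InfeasibleDesignError(DegOverlapError, ValueError):
    """A simulation design requests more planted structure than fits."""


class MembershipError(DegOverlapError, ValueError):
    """A gene set contains symbols outside the declared universe."""

    def __init__(self, offending, which="set"):
        offending = sorted(offending)
        shown = ", ".join(offending[:10])
        more = f" (+{len(offending) - 10} more)" if len(offending) > 10 else ""
        super().__init__(
            f"{which} contains {len(offending)} symbol(s) outside the "
            f"universe: {shown}{more}"
        )
        self.offending = offending


class ConfigurationError(DegOverlapError, ValueError):
    """A configuration file or column mapping cannot be interpreted."""


class ParseError(DegOverlapError, ValueError):
    """An input table contains cells that cannot be parsed."""
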