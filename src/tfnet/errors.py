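"""Exception hierarchy.

All errors derive from :class:`TfnetError` so callers can catch pipeline
failures with a single except clause; the subclasses distinguish bad
configuration values, violated data contracts, and unknown identifiers.
"""


class TfnetError(Exception):
    """Base class for all tfnet errors."""


class ConfigError(TfnetError, ValueError):
    """A configuration value is out of range or inconsistent."""


class ContractError(TfnetError, ValueError):
    """An input violates a documented data contract (e.g. query not a
    subset of the universe)."""


class UnknownIdentifierError(TfnetError, KeyError):
    """A requested identifier is absent from the data it should index."""


class PreconditionError(TfnetError, ValueError):
    """An operation's precondition does not hold (e.g. too few replicates)."""
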