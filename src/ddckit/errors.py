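"""Exception hierarchy for ddckit.

All package-specific errors derive from :class:`DdckitError` so callers can
catch the whole family with one clause.
"""


class DdckitError(Exception):
    """Base class for all ddckit errors."""


class EncodingError(DdckitError, ValueError):
    """A character cannot be represented under the active encoding scheme."""


class CapacityError(DdckitError, ValueError):
    """A word or index does not fit the carrier's bit array."""


class StateError(DdckitError, RuntimeError):
    """An operation was applied to a grid in the wrong scramble state."""


class DesignError(DdckitError, ValueError):
    """A carrier design is malformed or an index lies outside its lattice."""


class ModeError(DdckitError, ValueError):
    """A key is used in a mode (abstract/sequence) it does not support."""


class DerivationError(DdckitError, ValueError):
    """A user key cannot be derived from the given design and scaffold."""


class ParameterError(DdckitError, ValueError):
    """A numeric parameter is outside its valid range."""


class UndefinedYieldError(DdckitError, ValueError):
    """A yield was requested for an empty observation set (N = 0)."""
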