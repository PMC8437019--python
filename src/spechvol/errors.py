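"""Exception hierarchy shared across the package."""


class SpechvolError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SpechvolError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(SpechvolError, ValueError):
    """An input file does not conform to the expected layout."""


class DegenerateDataError(SpechvolError, ValueError):
    """Data are degenerate for the requested estimator (e.g. zero spread)."""


class ProtocolError(SpechvolError, ValueError):
    """A plot fails the sampling-protocol preconditions."""
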