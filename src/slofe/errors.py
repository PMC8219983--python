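"""Exception types shared across the package."""


class SlofeError(Exception):
    """Base class for all package errors."""


class FormatError(SlofeError, ValueError):
    """An input file violates its format contract."""


class CrossReferenceError(SlofeError, KeyError):
    """An identifier refers to a record that does not exist."""


class EmptyStemLoopError(SlofeError, ValueError):
    """An operation received a stem-loop with no paired positions."""


class ConfigurationError(SlofeError, RuntimeError):
    """A requested backend or option is unavailable."""


class GenerationError(SlofeError, RuntimeError):
    """The synthetic-fixture generator could not satisfy its constraints."""
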