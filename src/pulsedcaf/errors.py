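"""Exception hierarchy shared across the package."""


class PulsedcafError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PulsedcafError):
    """A file does not conform to the expected tabular dialect
    (e.g. a mandatory column is absent)."""


class ParseError(PulsedcafError):
    """A cell value cannot be interpreted; message carries row/column
    coordinates where applicable."""


class ConfigurationError(PulsedcafError):
    """A parameter, design or config object violates its domain."""


class NumericalError(PulsedcafError):
    """A statistical routine cannot proceed (e.g. no usable variance)."""
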