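"""Exception hierarchy shared across the package."""


class ActinometError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ActinometError, ValueError):
    """A file or table does not conform to the expected layout."""


class FormulaError(FormatError):
    """A molecular formula string cannot be parsed."""


class ConfigurationError(ActinometError, ValueError):
    """Invalid parameters or an operation applied to unsuitable inputs."""


class DataError(ActinometError, ValueError):
    """Values violate a domain invariant (negative zones, zero variance, ...)."""


class StratificationError(ConfigurationError):
    """A cross-validation fold would remove an entire class from training."""
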