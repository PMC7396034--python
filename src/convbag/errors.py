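"""Exception hierarchy shared across the package."""


class ConvbagError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ConvbagError):
    """An option, spec field or architecture parameter is out of range."""


class SchemaError(ConvbagError):
    """Input table columns do not match what a fitted object expects."""


class DegenerateLabelError(ConvbagError):
    """An operation that needs both classes received a single-class input."""


class EmptyOutputError(ConvbagError):
    """A filtering step removed every row."""


class ArchitectureError(ConvbagError):
    """Tensor shapes are inconsistent with the network layout."""


class DivergenceError(ConvbagError):
    """Training produced non-finite losses or gradients."""


class UsageError(ConvbagError):
    """An operation was called out of order (e.g. predict before fit)."""
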