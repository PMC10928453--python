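"""Exception hierarchy shared by all irsurv modules."""


class IrsurvError(Exception):
    """Base class for all irsurv errors."""


class FormatError(IrsurvError):
    """A file does not conform to its declared on-disk format."""


class DataError(IrsurvError):
    """Values violate a domain invariant (non-finite, time <= 0, ...)."""


class ConfigError(IrsurvError):
    """A configuration value or combination of values is invalid."""


class DegenerateInputError(IrsurvError):
    """Input is structurally valid but admits no meaningful answer."""


class ConvergenceError(IrsurvError):
    """An iterative solver failed to converge within its iteration budget."""
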