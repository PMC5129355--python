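"""Exception hierarchy."""


class GeoordinalError(Exception):
    """Base class for package errors."""


class ConfigurationError(GeoordinalError, ValueError):
    """A model or simulation specification is internally inconsistent."""


class DataError(GeoordinalError, ValueError):
    """Observed data violate a declared contract (unseen level, bad label...)."""


class DomainError(GeoordinalError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class NumericsError(GeoordinalError, ArithmeticError):
    """A linear-algebra step failed (rank deficiency, indefinite penalty...)."""
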