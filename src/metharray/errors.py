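"""Exception hierarchy shared across the package."""


class MetharrayError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MetharrayError):
    """A simulation or analysis configuration is invalid or infeasible."""


class FormatError(MetharrayError):
    """An input file violates its declared format."""


class IntegrityError(MetharrayError):
    """Inputs are structurally valid but mutually inconsistent or empty."""


class CoordinateError(MetharrayError):
    """A genomic interval falls outside chromosome bounds."""
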