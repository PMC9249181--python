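"""Exception types raised by the model."""


class SamsceError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(SamsceError):
    """A polygon or axis construction is ill-posed (too few points, collinear...)."""


class DegenerateGeometryError(SamsceError):
    """Coincident nodes where distinct positions are required."""


class SingularConfigurationError(SamsceError):
    """Pair interaction evaluated at zero separation."""


class NumericalBlowupError(SamsceError):
    """A node position became non-finite during integration."""


class InvalidTissueError(SamsceError):
    """Tissue-level precondition violated (e.g. no L1 cells)."""


class ConfigError(SamsceError):
    """Invalid or inconsistent simulation configuration."""


class AreaWindowError(SamsceError):
    """No node pair satisfies the even-area constraint, even after widening."""
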