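"""Exception hierarchy for the pnpcyto pipeline."""


class PnpCytoError(Exception):
    """Base class for all pipeline errors."""


class CalibrationError(PnpCytoError):
    """Color-compensation calibration failed (bad bead slide, rank-deficient matrix)."""


class InputError(PnpCytoError):
    """Malformed or inconsistent input data."""


class ParameterError(PnpCytoError):
    """A configuration value is incompatible with the data it is applied to."""


class DataError(PnpCytoError):
    """A dataset does not satisfy the preconditions of an operation."""
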