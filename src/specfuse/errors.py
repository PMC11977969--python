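"""Exception hierarchy shared across the package."""


class SpecFuseError(Exception):
    """Base class for all specfuse errors."""


class FormatError(SpecFuseError):
    """Malformed input file (ragged rows, unsortable axis, mixed series lengths)."""


class LabelledDataError(SpecFuseError):
    """Spectral data lacking, or with invalid, concentration labels."""


class StratificationError(SpecFuseError):
    """A concentration level has too few replicates for the requested split."""


class ParameterError(SpecFuseError):
    """An out-of-range or inconsistent algorithm parameter."""


class DegenerateInputError(SpecFuseError):
    """Input on which the operation is mathematically undefined (zero variance etc.)."""


class NumericError(SpecFuseError):
    """Non-finite values or numerically unstable computation."""


class ShapeError(SpecFuseError):
    """Mismatched array dimensions between coupled inputs."""


class AlignmentError(SpecFuseError):
    """Sample identities/order differ between sets that must be paired."""


class SelectionError(SpecFuseError):
    """Invalid channel-selection indices (out of range, duplicated)."""


class CompatibilityError(SpecFuseError):
    """Axes or preprocessing states incompatible between calibration and prediction data."""


class InstabilityError(SpecFuseError):
    """Too many sampled models produced non-finite cross-validation errors."""
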