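"""Exception hierarchy shared across the package."""


class EEGFusionError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(EEGFusionError, ValueError):
    """A numeric or structural argument violates a precondition."""


class UnknownMontageError(EEGFusionError, KeyError):
    """Requested electrode montage is not shipped with the package."""


class FormatError(EEGFusionError):
    """An on-disk container is missing a required group/attribute."""


class InvalidBandError(InvalidArgumentError):
    """A frequency band is empty, inverted, or exceeds Nyquist."""


class MappingError(EEGFusionError, KeyError):
    """A channel name has no cell in the electrode grid map."""


class InsufficientWindowsError(InvalidArgumentError):
    """Fewer DE windows than the requested temporal depth."""


class DegenerateInputError(InvalidArgumentError):
    """Input is constant / zero-variance where variability is required."""


class ShapeError(InvalidArgumentError):
    """Array shape does not match the model configuration."""
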