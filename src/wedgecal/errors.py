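"""Exception hierarchy for the film-calibration pipeline."""


class WedgecalError(Exception):
    """Base class for all package errors."""


class FormatError(WedgecalError):
    """File missing, not a readable RGB TIFF, or missing the requested channel."""


class DimensionError(WedgecalError):
    """Raster/stack shape mismatch or raster too small for the operation."""


class BoundsError(WedgecalError):
    """Requested ROI falls (partially) outside the raster."""


class DomainError(WedgecalError, ValueError):
    """Input outside the mathematical domain of an operation."""


class SegmentationError(WedgecalError):
    """No field edges detectable above the noise floor."""


class RegistrationError(WedgecalError):
    """Film profile and reference profile supports do not overlap."""


class ExtrapolationError(WedgecalError):
    """Positions requested outside the support of a reference profile."""


class FitError(WedgecalError):
    """Calibration fit failed to converge or the design is rank deficient."""


class ConfigError(WedgecalError):
    """Invalid run configuration."""


class RotationWarning(UserWarning):
    """The two field-edge gradient widths differ enough to suggest a rotated film."""
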