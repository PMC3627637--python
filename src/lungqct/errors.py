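"""Exception hierarchy for the lungqct pipeline.

Every error a caller can meaningfully branch on gets its own class; all
inherit from :class:`LungQCTError` so batch drivers can catch the family.
"""


class LungQCTError(Exception):
    """Base class for all lungqct errors."""


class ValidationError(LungQCTError, ValueError):
    """An input violates a documented precondition or type invariant."""


class EmptySegmentationError(ValidationError):
    """A lung mask contains no voxels; densitometry is undefined."""


class AlignmentError(ValidationError):
    """A mask and its companion volume have mismatched shapes."""


class DegenerateAttenuationError(LungQCTError, ArithmeticError):
    """Mean lung attenuation is too close to zero for a stable E/I ratio."""


class NoNonEmphysematousLungError(LungQCTError, ArithmeticError):
    """All lung voxels fall below -950 HU; the relative-volume denominator is empty."""


class ZeroVarianceError(LungQCTError, ValueError):
    """A vector is constant; correlation or standardization is undefined."""


class DegenerateRegressionError(LungQCTError, ValueError):
    """The regression predictor is constant; the slope is unidentified."""


class CollinearityError(LungQCTError, ValueError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class InsufficientDuplicatesError(ValidationError):
    """Fewer than three duplicate-scan pairs; rank correlation is meaningless."""


class ScanReadError(LungQCTError, IOError):
    """A volume or mask file is missing, unreadable, or internally inconsistent."""

    def __init__(self, message: str, subject_id=None, phase=None):
        super().__init__(message)
        self.subject_id = subject_id
        self.phase = phase


class ConfigError(ValidationError):
    """A run configuration is internally inconsistent."""
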