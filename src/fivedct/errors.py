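"""Exception hierarchy for the 5DCT workflow.

Every failure mode that a pipeline stage is contractually required to
signal gets its own class so callers can react to the specific condition
(drop a scan, fall back to a backup protocol, abort the session).
"""


class FiveDCTError(Exception):
    """Base class for all workflow errors."""


class InvalidSpecError(FiveDCTError):
    """A simulation or configuration object violates its own invariants."""


class OutOfRangeError(FiveDCTError):
    """A requested time or index falls outside the available data."""


class UnderDeterminedSessionError(FiveDCTError):
    """Fewer scans than the motion model has coefficient vectors per voxel."""


class UnusableReferenceError(FiveDCTError):
    """The reference scan failed a validation check and cannot anchor the session."""


class InsufficientDataError(FiveDCTError):
    """Not enough samples for the requested operation."""


class DegenerateCorrelationError(FiveDCTError):
    """Correlation undefined (a constant input)."""


class NoBreathsDetectedError(FiveDCTError):
    """Breath segmentation found no exhalation minima."""


class InsufficientBreathsError(FiveDCTError):
    """Too few segmented breaths to build a representative breath."""


class ExcessiveNoiseError(FiveDCTError):
    """Scanner on/off signal too noisy for reliable edge detection."""


class SyncError(FiveDCTError):
    """Scan windows and scans cannot be matched, or slice tags are missing."""


class GeometryError(FiveDCTError):
    """Volumes do not share a common grid, or a shift exceeds the allowed bound."""


class RegistrationFailedError(FiveDCTError):
    """External DIR adapter failed; carries the tool output when available."""

    def __init__(self, message: str, tool_output: str | None = None):
        super().__init__(message)
        self.tool_output = tool_output


class EmptyMaskError(FiveDCTError):
    """Lung masking produced no voxels."""


class UndefinedCorrelationError(FiveDCTError):
    """Rank correlation undefined (constant ranks)."""


class RankDeficiencyError(FiveDCTError):
    """Regression design matrix is rank deficient."""


class EmptyInputError(FiveDCTError):
    """An operation received an empty record set."""
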