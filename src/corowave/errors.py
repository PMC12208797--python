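"""Exception hierarchy for the corowave pipeline.

Every failure mode raised by the package derives from :class:`CorowaveError`
so callers can catch pipeline problems without masking programming errors.
"""


class CorowaveError(Exception):
    """Base class for all corowave errors."""


class ParameterError(CorowaveError, ValueError):
    """A generator or analysis parameter violates its stated bounds."""


class GenerationError(CorowaveError):
    """Synthetic-cohort constraints could not be satisfied."""


class FormatError(CorowaveError, ValueError):
    """A trace file is malformed or missing a required channel."""


class InsufficientDataError(CorowaveError):
    """A series is too short for the requested operation."""


class SegmentationError(CorowaveError):
    """Beat detection failed (fewer than two onsets found)."""


class SelectionError(CorowaveError):
    """No valid rest/hyperemia analysis window could be selected."""

    def __init__(self, message: str, trace: str = ""):
        super().__init__(message)
        self.trace = trace


class InsufficientBeatsError(CorowaveError):
    """Fewer accepted beats than required for ensemble averaging."""

    def __init__(self, n_accepted: int, n_required: int = 8):
        super().__init__(
            f"only {n_accepted} accepted beats; at least {n_required} required"
        )
        self.n_accepted = n_accepted
        self.n_required = n_required


class DegenerateSignalError(CorowaveError):
    """A signal is flat or otherwise carries no usable information."""


class MissingWaveError(CorowaveError):
    """A required wave (e.g. the backward expansion wave) was not found."""


class PairingError(CorowaveError, ValueError):
    """Paired samples have mismatched lengths."""


class DegenerateTableError(CorowaveError):
    """A contingency table has an empty margin or zero total."""
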