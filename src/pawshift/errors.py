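"""Exception and warning types shared across the package."""


class PawshiftError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PawshiftError, ValueError):
    """An argument violates a documented precondition."""


class DesignError(PawshiftError, ValueError):
    """A cohort design table is inconsistent (e.g., duplicate trials)."""


class TrackingFormatError(PawshiftError, ValueError):
    """A tracking table does not conform to the three-header-row CSV dialect."""


class ManifestError(PawshiftError, ValueError):
    """A cohort manifest is malformed or references invalid conditions/files."""


class UnusableTrackError(PawshiftError, ValueError):
    """A track has no sample above the confidence threshold."""


class NoUsableTrialsError(PawshiftError, ValueError):
    """A mouse has zero usable trials for a requested condition."""


class PipelineError(PawshiftError, RuntimeError):
    """A pipeline stage failed; carries the stage name and trial identity."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        self.detail = detail
        super().__init__(f"[{stage}] {detail}")


class DegenerateDataWarning(UserWarning):
    """Emitted when a statistical test is run on degenerate data."""
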