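"""Exception hierarchy for the analysis pipeline."""


class FractalvocError(Exception):
    """Base class for all package errors."""


class InputError(FractalvocError):
    """A file or value supplied by the user is unreadable or malformed."""


class FormatError(InputError):
    """An audio file uses an encoding the reader does not support."""


class IneligibleRecordingError(FractalvocError):
    """A recording fails an eligibility rule (length, band coverage, ...).

    Carries ``reason`` so pipelines can report why each recording was skipped.
    """

    def __init__(self, reason: str, recording_id: str = ""):
        self.reason = reason
        self.recording_id = recording_id
        super().__init__(f"{recording_id or 'recording'}: {reason}")


class DomainError(FractalvocError, ValueError):
    """A numeric argument lies outside the mathematically valid domain."""


class ConvergenceError(FractalvocError):
    """The sampler hit its iteration cap before meeting the stopping rule.

    ``partial`` holds whatever state was accumulated, for diagnosis.
    """

    def __init__(self, message: str, partial=None):
        self.partial = partial
        super().__init__(message)


class UsageError(FractalvocError):
    """An API was called with inconsistent arguments (e.g. mismatched ids)."""
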