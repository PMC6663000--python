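"""Exception hierarchy.

Every error raised on a user-facing code path derives from
:class:`SporegateError`, so callers can catch one type at the pipeline
boundary while tests assert on the specific subclass.
"""


class SporegateError(Exception):
    """Base class for all package errors."""


class FormatError(SporegateError):
    """File is not a readable FCS list-mode file (truncated, bad header...)."""


class UnsupportedModeError(FormatError):
    """FCS file is readable but not a supported dialect (mode/datatype)."""


class ValidationError(SporegateError):
    """An argument violates a documented precondition."""


class ChannelLookupError(ValidationError):
    """A named channel is not present in the event table."""


class SampleSizeError(ValidationError):
    """Too few events for the requested fit."""


class DegeneracyError(SporegateError):
    """A fit collapsed (singular covariance, variance floor, equal means)."""


class NoRootError(SporegateError):
    """The component-density difference has no sign change in the bracket."""


class MappingError(SporegateError):
    """Cluster-to-biological-label mapping is ambiguous."""


class ConfigurationError(SporegateError):
    """Pipeline configuration is inconsistent (missing reference sample...)."""


class PipelineError(SporegateError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")
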