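"""Typed exceptions shared across the pipeline.

Every reader, generator and fitting routine raises one of these instead of
letting a bare ``KeyError``/``IndexError`` escape, so the CLI can map error
classes onto exit codes.
"""


class LRCrosstalkError(Exception):
    """Base class for all package errors."""


class FormatError(LRCrosstalkError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(LRCrosstalkError):
    """In-memory data violates an invariant (negative counts, bad labels...)."""


class ConfigurationError(LRCrosstalkError):
    """A simulation or run configuration is internally inconsistent."""


class EmptyResultError(LRCrosstalkError):
    """An operation produced an empty result where downstream stages need one."""


class ConvergenceError(LRCrosstalkError):
    """An iterative fit failed to converge within its iteration budget."""


class StageError(LRCrosstalkError):
    """A pipeline stage failed; wraps the underlying cause with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause!r}")
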