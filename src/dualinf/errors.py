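"""Exception types shared across the package."""


class DualInfError(Exception):
    """Base class for package errors."""


class MalformedOutputError(DualInfError):
    """Backend text could not be parsed into the structured output grammar.

    Carries the raw text so the caller can retry once or record a
    parsing failure for the case.
    """

    def __init__(self, message: str, raw: str = ""):
        super().__init__(message)
        self.raw = raw


class TemplateError(DualInfError):
    """Unknown template or unbound placeholder during prompt rendering."""


class ConfigurationError(DualInfError):
    """Invalid configuration: unknown variant, empty knowledge base, bad rates."""


class UndefinedMetricError(DualInfError):
    """A metric is undefined on the given inputs (e.g. zero denominator)."""


class ValidationError(DualInfError):
    """A serialized record violates the dataset schema."""

    def __init__(self, message: str, record_index: int | None = None, field: str | None = None):
        super().__init__(message)
        self.record_index = record_index
        self.field = field
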