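"""Exception hierarchy shared across the package.

``ValidationError`` covers bad user input (malformed files, inconsistent
tables); ``PipelineError`` covers runtime failures after validation. The CLI
maps them to exit codes 1 and 2 respectively.
"""


class MndkitError(Exception):
    """Base class for all package errors."""


class ValidationError(MndkitError, ValueError):
    """Input failed validation (bad file content, inconsistent model)."""


class VcfParseError(ValidationError):
    """A VCF could not be parsed."""


class PipelineError(MndkitError, RuntimeError):
    """Runtime failure in an otherwise-valid pipeline run."""
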