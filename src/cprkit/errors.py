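"""Exception hierarchy shared across the package.

Validation is total: malformed inputs raise one of these typed errors,
never a silent coercion. The CLI maps :class:`ValidationError` subclasses
to exit code 2 and everything else to exit code 1.
"""


class CprkitError(Exception):
    """Base class for all package errors."""


class ValidationError(CprkitError):
    """Input failed validation against its declared contract."""


class FormatError(ValidationError):
    """A file or table is structurally malformed (duplicate ids, bad cells)."""


class VocabularyError(ValidationError):
    """A value falls outside a closed controlled vocabulary."""


class ConfigError(ValidationError):
    """A configuration object is internally inconsistent."""
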