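"""Exception hierarchy shared across the package."""


class LungPrepError(Exception):
    """Base class for all package errors."""


class ValidationError(LungPrepError, ValueError):
    """Input or configuration violates a documented precondition."""


class FormatError(LungPrepError, ValueError):
    """A file exists but is not in a supported image format/layout."""


class NoBodyError(ValidationError):
    """The dense-tissue mask contains no connected component to call a body."""
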