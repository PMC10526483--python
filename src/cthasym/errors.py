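"""Exception hierarchy shared by all modules."""


class CthAsymError(Exception):
    """Base class for all package errors."""


class FormatError(CthAsymError):
    """A file or table does not conform to the expected dialect."""


class ValidationError(CthAsymError, ValueError):
    """A value violates a domain invariant (range, uniqueness, schema)."""


class DomainError(CthAsymError, ValueError):
    """An operation was called outside its mathematical domain."""
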