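"""Exception hierarchy.

Every error raised by pepcover derives from :class:`PepcoverError`, so callers
(and the CLI) can catch one type. Subclasses mirror the failure categories of
the pipeline stages: unsupported platforms, file schema problems, modification
notation problems, residue alphabet violations, dangling cross-references,
invalid configuration, and invalid data values.
"""


class PepcoverError(Exception):
    """Base class for all pepcover errors."""


class UnsupportedPlatformError(PepcoverError):
    """An unknown search-engine platform identifier was requested."""


class SchemaError(PepcoverError):
    """A file is missing a mandatory column/section, or a required key is absent."""


class FormatError(PepcoverError):
    """A file could not be parsed at all (e.g. malformed XML)."""


class NotationError(PepcoverError):
    """A modified peptide string violates its modification grammar."""

    def __init__(self, message: str, offset: int | None = None):
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)
        self.offset = offset


class AlphabetError(PepcoverError):
    """A sequence contains a character outside the residue alphabet."""


class CrossReferenceError(PepcoverError):
    """A reference (peptide id, target id) does not resolve."""


class ConfigurationError(PepcoverError):
    """User-supplied options are inconsistent or incomplete."""


class DataError(PepcoverError):
    """A data value violates a contract (e.g. negative quantity)."""
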