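"""Exception hierarchy.

Every error the library raises deliberately derives from :class:`ZonalSpaceError`
so the CLI can map them to a non-zero exit code uniformly.
"""


class ZonalSpaceError(Exception):
    """Base class for all errors raised by zonalspace."""


class InputFormatError(ZonalSpaceError):
    """Malformed or inconsistent input file (matrix, barcodes, features...)."""


class ConfigError(ZonalSpaceError):
    """Invalid zone-marker-gene configuration."""


class ParameterError(ZonalSpaceError):
    """Parameter outside its documented domain."""


class GeneLookupError(ZonalSpaceError, KeyError):
    """Requested gene symbol absent from the matrix."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class ConsistencyError(ZonalSpaceError):
    """Objects that must refer to the same dataset do not."""


class NormalizationError(ZonalSpaceError):
    """A cell violates the normalization preconditions (e.g. all-zero counts)."""
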