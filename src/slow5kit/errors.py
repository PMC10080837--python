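"""Exception hierarchy for slow5kit.

Every error raised by the library derives from :class:`Slow5Error` so callers
(and the CLI) can catch format problems without catching programming errors.
"""


class Slow5Error(Exception):
    """Base class for all slow5kit errors."""


class CalibrationError(Slow5Error):
    """Degenerate calibration scalars (e.g. non-positive digitisation)."""


class FieldOverflowError(Slow5Error):
    """A field value cannot be represented in the binary layout."""


class UnsupportedEncodingError(Slow5Error):
    """Unknown record- or signal-compression method."""


class CorruptSignalError(Slow5Error):
    """Encoded signal bytes are truncated or decode outside int16."""


class CorruptRecordError(Slow5Error):
    """A record payload is truncated, has trailing bytes, or mismatches the schema."""


class CorruptBlockError(Slow5Error):
    """A record-layer compressed block is not a valid zlib/zstd stream."""


class ParseError(Slow5Error):
    """SLOW5 ASCII parse failure; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NotABlow5Error(Slow5Error):
    """File does not begin with the BLOW5 magic."""


class TruncationError(Slow5Error):
    """BLOW5 file ends mid-frame or without the EOF marker."""


class CorruptIndexError(Slow5Error):
    """Index file has a bad magic or malformed entries."""


class StaleIndexError(Slow5Error):
    """Index was built against a data file of a different size."""


class DuplicateReadIdError(Slow5Error):
    """The same read_id occurs twice in one file (detected at index time)."""


class ReadIdNotFoundError(Slow5Error):
    """Requested read_id is absent from the index."""


class MetadataMismatchError(Slow5Error):
    """cat refused: inputs do not share identical headers/compression."""


class SchemaConflictError(Slow5Error):
    """merge refused: inputs carry conflicting auxiliary schemas."""


class MalformedFast5Error(Slow5Error):
    """A FAST5 read group lacks its signal dataset or calibration attributes."""
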