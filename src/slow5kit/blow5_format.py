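"""The binary BLOW5 container.

File layout (little-endian throughout; normative byte layout in
``docs/format.md``):

    magic (8 bytes) | record-method byte | signal-method byte |
    header_length uint32 | header block (SLOW5 ASCII header text,
    uncompressed) | record frames | EOF marker (8 bytes)

Each record frame is a uint32 byte length followed by the compressed record
payload. Frames are the unit a batch reader fetches, so decompression and
parsing can be farmed out while the output preserves input order.
"""

from __future__ import annotations

import io
import struct
from collections.abc import Iterable, Iterator
from pathlib import Path

from . import codec
from .ascii_format import header_text, parse_header_text
from .errors import NotABlow5Error, Slow5Error, TruncationError
from .model import (
    CompressionSpec,
    DEFAULT_SPEC,
    FileHeader,
    RecordCompression,
    SignalCompression,
    SignalRecord,
    validate_record,
)

MAGIC = b"\x8aBLOW5\r\n"
EOF_MARKER = b"\x8a5EOF\r\n\x00"
assert len(MAGIC) == 8 and len(EOF_MARKER) == 8 and MAGIC != EOF_MARKER

_RECORD_METHOD_BYTE = {
    RecordCompression.NONE: 0,
    RecordCompression.ZLIB: 1,
    RecordCompression.ZSTD: 2,
}
_SIGNAL_METHOD_BYTE = {
    SignalCompression.NONE: 0,
    SignalCompression.SVB_ZD: 1,
}
_RECORD_METHOD_FROM_BYTE = {v: k for k, v in _RECORD_METHOD_BYTE.items()}
_SIGNAL_METHOD_FROM_BYTE = {v: k for k, v in _SIGNAL_METHOD_BYTE.items()}

#: Records fetched per batch when none is specified.
DEFAULT_BATCH_SIZE = 4096

#: I/O buffer for linear passes (stats, indexing).
IO_BUFFER_SIZE = 128 * 1024


def encode_frame(
    record: SignalRecord, header: FileHeader, spec: CompressionSpec
) -> bytes:
    """Pack + compress one record into a length-prefixed frame."""
    payload = codec.pack_record(record, header, spec.signal_method)
    compressed = codec.compress_block(payload, spec.record_method)
    return struct.pack("<I", len(compressed)) + compressed


def decode_frame(
    frame: bytes, header: FileHeader, spec: CompressionSpec
) -> SignalRecord:
    """Inverse of :func:`encode_frame` (frame includes its length prefix)."""
    if len(frame) < 4:
        raise TruncationError("frame shorter than its length prefix")
    (length,) = struct.unpack("<I", frame[:4])
    if len(frame) != 4 + length:
        raise TruncationError(
            f"frame is {len(frame)} bytes, prefix declares {4 + length}"
        )
    payload = codec.decompress_block(frame[4:], spec.record_method)
    return codec.unpack_record(payload, header, spec.signal_method)


def write_blow5(
    header: FileHeader,
    records: Iterable[SignalRecord],
    sink,
    spec: CompressionSpec = DEFAULT_SPEC,
) -> int:
    """Write a complete BLOW5 file; returns the record count."""
    if isinstance(sink, (str, Path)):
        with open(sink, "wb") as fh:
            return write_blow5(header, records, fh, spec)
    block = header_text(header).encode("utf-8")
    sink.write(MAGIC)
    sink.write(bytes([_RECORD_METHOD_BYTE[spec.record_method]]))
    sink.write(bytes([_SIGNAL_METHOD_BYTE[spec.signal_method]]))
    sink.write(struct.pack("<I", len(block)))
    sink.write(block)
    count = 0
    for record in records:
        report = validate_record(record, header)
        if not report.ok:
            raise Slow5Error(
                f"record {record.read_id!r} failed validation: "
                + "; ".join(report.violations)
            )
        sink.write(encode_frame(record, header, spec))
        count += 1
    sink.write(EOF_MARKER)
    return count


class Blow5Reader:
    """Open BLOW5 file: parsed header plus lazy/batch access to frames.

    The reader validates the magic and header block eagerly; frames are
    decompressed on demand. ``data_end`` is the offset of the EOF marker,
    so truncation (a missing marker or a frame running past it) is detected
    deterministically.
    """

    def __init__(self, source):
        if isinstance(source, (str, Path)):
            self._fh = open(source, "rb", buffering=IO_BUFFER_SIZE)
            self._own = True
        else:
            self._fh = source
            self._own = False
        self._fh.seek(0, io.SEEK_END)
        self.file_size = self._fh.tell()
        self._fh.seek(0)
        head = self._fh.read(8)
        if head != MAGIC:
            raise NotABlow5Error(f"bad magic {head!r}")
        methods = self._fh.read(2)
        rest = self._fh.read(4)
        if len(methods) != 2 or len(rest) != 4:
            raise TruncationError("file ends inside the fixed header")
        try:
            record_method = _RECORD_METHOD_FROM_BYTE[methods[0]]
            signal_method = _SIGNAL_METHOD_FROM_BYTE[methods[1]]
        except KeyError:
            raise NotABlow5Error(
                f"unknown compression method bytes {methods!r}"
            ) from None
        self.spec = CompressionSpec(record_method, signal_method)
        (header_len,) = struct.unpack("<I", rest)
        self.header_block = self._fh.read(header_len)
        if len(self.header_block) != header_len:
            raise TruncationError("file ends inside the header block")
        self.header = parse_header_text(self.header_block.decode("utf-8"))
        self.header.compression = self.spec
        self.header_end = 8 + 2 + 4 + header_len
        self.data_end = self.file_size - len(EOF_MARKER)
        if self.data_end < self.header_end:
            raise TruncationError("file too short to hold an EOF marker")
        self._pos = self.header_end

    def close(self):
        if self._own:
            self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def _check_eof_marker(self):
        self._fh.seek(self.data_end)
        tail = self._fh.read(len(EOF_MARKER))
        if tail != EOF_MARKER:
            raise TruncationError("missing EOF marker")

    def next_batch(self, batch_size: int = DEFAULT_BATCH_SIZE):
        """Fetch up to *batch_size* raw frames without decompressing.

        Returns a list of (absolute offset of the frame's length prefix,
        frame bytes including the prefix); an empty list exactly at the end
        of the record region (after verifying the EOF marker).
        """
        if batch_size < 1:
            raise ValueError("batch_size must be positive")
        frames: list[tuple[int, bytes]] = []
        self._fh.seek(self._pos)
        while len(frames) < batch_size and self._pos < self.data_end:
            prefix = self._fh.read(4)
            if len(prefix) < 4 or self._pos + 4 > self.data_end:
                raise TruncationError("file ends inside a frame length prefix")
            (length,) = struct.unpack("<I", prefix)
            if self._pos + 4 + length > self.data_end:
                raise TruncationError("file ends inside a record frame")
            payload = self._fh.read(length)
            frames.append((self._pos, prefix + payload))
            self._pos += 4 + length
        if not frames:
            self._check_eof_marker()
        return frames

    def frames(self) -> Iterator[tuple[int, bytes]]:
        """All remaining frames, in file order."""
        while True:
            batch = self.next_batch()
            if not batch:
                return
            yield from batch

    def records(self) -> Iterator[SignalRecord]:
        """Decode all remaining records, in file order."""
        for _, frame in self.frames():
            yield decode_frame(frame, self.header, self.spec)


def open_blow5(source) -> tuple[FileHeader, Iterator[SignalRecord]]:
    """Open a BLOW5 file; returns (header with CompressionSpec, lazy records)."""
    reader = Blow5Reader(source)

    def gen():
        with reader:
            yield from reader.records()

    return reader.header, gen()


def read_blow5_all(source) -> tuple[FileHeader, list[SignalRecord]]:
    header, records = open_blow5(source)
    return header, list(records)
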