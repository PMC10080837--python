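"""Random-access index: read_id -> (byte offset, frame length).

The index is a binary sidecar (``<data file>.idx``) holding one entry per
record in file order. Building it needs each record's read_id only, so the
record layer is decompressed just far enough to cover it (partial
decompression under zlib; zstd forces a full decompression). The sidecar
records the source file's byte size as a staleness check — modification
times are not trusted.

Sidecar layout (little-endian): magic ``SLOW5IDX`` | uint64 source size |
uint64 entry count | entries (uint16 id length, id bytes, uint64 offset,
uint64 length). ASCII SLOW5 files are indexable too: offsets address line
starts and lengths are line lengths (including the newline).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

from . import codec
from .ascii_format import parse_record_row, read_slow5
from .blow5_format import Blow5Reader, decode_frame
from .errors import (
    CorruptIndexError,
    DuplicateReadIdError,
    ReadIdNotFoundError,
    StaleIndexError,
    TruncationError,
)
from .model import FileHeader, SignalRecord

INDEX_MAGIC = b"SLOW5IDX"


@dataclass(frozen=True)
class IndexEntry:
    read_id: str
    offset: int  # byte position of the record's frame (or text line)
    length: int  # frame byte length, length prefix included


def _is_blow5(path: Path) -> bool:
    from .blow5_format import MAGIC

    with open(path, "rb") as fh:
        return fh.read(8) == MAGIC


def default_index_path(data_path) -> Path:
    p = Path(data_path)
    return p.with_name(p.name + ".idx")


def _iter_blow5_entries(reader: Blow5Reader, force_full_decompression: bool):
    for offset, frame in reader.frames():
        if force_full_decompression:
            read_id = decode_frame(frame, reader.header, reader.spec).read_id
        else:
            read_id = codec.peek_read_id(frame[4:], reader.spec.record_method)
        yield IndexEntry(read_id, offset, len(frame))


def _iter_slow5_entries(path: Path):
    offset = 0
    with open(path, "rb") as fh:
        for raw in fh:
            line = raw.decode("utf-8").rstrip("\r\n")
            if line.startswith(("#", "@")) or line == "":
                offset += len(raw)
                continue
            read_id = line.split("\t", 1)[0]
            yield IndexEntry(read_id, offset, len(raw))
            offset += len(raw)


def build_index(
    data_path,
    index_path=None,
    force_full_decompression: bool = False,
) -> Path:
    """Build the sidecar index for a SLOW5/BLOW5 file; returns its path.

    ``force_full_decompression`` disables the partial-decompression fast
    path; the emitted index is byte-identical either way.
    """
    from .toolkit import quickcheck

    data_path = Path(data_path)
    ok, defect = quickcheck(data_path)
    if not ok:
        raise TruncationError(f"refusing to index malformed file: {defect}")
    if index_path is None:
        index_path = default_index_path(data_path)
    if _is_blow5(data_path):
        with Blow5Reader(data_path) as reader:
            entries = list(_iter_blow5_entries(reader, force_full_decompression))
    else:
        entries = list(_iter_slow5_entries(data_path))
    seen: set[str] = set()
    for e in entries:
        if e.read_id in seen:
            raise DuplicateReadIdError(f"duplicate read_id {e.read_id!r}")
        seen.add(e.read_id)
    src_size = data_path.stat().st_size
    with open(index_path, "wb") as fh:
        fh.write(INDEX_MAGIC)
        fh.write(struct.pack("<QQ", src_size, len(entries)))
        for e in entries:
            id_bytes = e.read_id.encode("utf-8")
            fh.write(struct.pack("<H", len(id_bytes)))
            fh.write(id_bytes)
            fh.write(struct.pack("<QQ", e.offset, e.length))
    return Path(index_path)


def load_index(index_path, data_path) -> dict[str, IndexEntry]:
    """Load the sidecar into a read_id -> IndexEntry map.

    Raises :class:`StaleIndexError` if the data file's size no longer
    matches the size recorded at build time.
    """
    data_path = Path(data_path)
    with open(index_path, "rb") as fh:
        magic = fh.read(8)
        if magic != INDEX_MAGIC:
            raise CorruptIndexError(f"bad index magic {magic!r}")
        head = fh.read(16)
        if len(head) != 16:
            raise CorruptIndexError("index truncated in its header")
        src_size, count = struct.unpack("<QQ", head)
        current = data_path.stat().st_size
        if src_size != current:
            raise StaleIndexError(
                f"index built for a {src_size}-byte file; "
                f"{data_path} is now {current} bytes"
            )
        entries: dict[str, IndexEntry] = {}
        for _ in range(count):
            raw = fh.read(2)
            if len(raw) != 2:
                raise CorruptIndexError("index truncated in an entry")
            (id_len,) = struct.unpack("<H", raw)
            body = fh.read(id_len + 16)
            if len(body) != id_len + 16:
                raise CorruptIndexError("index truncated in an entry")
            read_id = body[:id_len].decode("utf-8")
            offset, length = struct.unpack("<QQ", body[id_len:])
            entries[read_id] = IndexEntry(read_id, offset, length)
    return entries


class RandomAccessor:
    """Single-seek record fetcher over an indexed SLOW5/BLOW5 file.

    Parses the header once at construction; each :meth:`get` then performs
    exactly one seek and one bounded read.
    """

    def __init__(self, data_path, index: dict[str, IndexEntry] | None = None):
        self.data_path = Path(data_path)
        if index is None:
            idx_path = default_index_path(self.data_path)
            if not idx_path.exists():
                build_index(self.data_path, idx_path)
            index = load_index(idx_path, self.data_path)
        self.index = index
        self._binary = _is_blow5(self.data_path)
        if self._binary:
            reader = Blow5Reader(self.data_path)
            self.header: FileHeader = reader.header
            self._spec = reader.spec
            reader.close()
        else:
            self.header, _ = read_slow5(self.data_path)
            self._spec = None
        self._fh = open(self.data_path, "rb")
        self.seeks = 0  # instrumentation: bounded-read contract

    def close(self):
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def get(self, read_id: str) -> SignalRecord:
        try:
            entry = self.index[read_id]
        except KeyError:
            raise ReadIdNotFoundError(f"read_id {read_id!r} not in index") from None
        self._fh.seek(entry.offset)
        chunk = self._fh.read(entry.length)
        self.seeks += 1
        if len(chunk) != entry.length:
            raise TruncationError(f"short read at offset {entry.offset}")
        if self._binary:
            return decode_frame(chunk, self.header, self._spec)
        return parse_record_row(
            chunk.decode("utf-8").rstrip("\r\n"), self.header
        )


def fetch_by_read_id(
    data_path, index: dict[str, IndexEntry], read_id: str
) -> SignalRecord:
    """Fetch one record by read_id with a single seek + bounded read."""
    with RandomAccessor(data_path, index) as acc:
        return acc.get(read_id)
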