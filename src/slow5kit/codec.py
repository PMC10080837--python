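"""Record serialization and the two compression layers.

Signal layer: ``svb-zd`` — samples are widened to 32 bits, delta-coded
(d0 = s0), zig-zag mapped to unsigned, then stream-variable-byte packed:
ceil(n/4) control bytes (value i's 2-bit byte-length-minus-one field sits at
bit 2*(i mod 4), low bits first) followed by the little-endian data bytes.

Record layer: the packed payload is block-compressed with zlib or zstd (or
left as-is). zlib streams support partial decompression, which
:func:`peek_read_id` exploits to read only the leading read_id; zstd does
not, so it falls back to full decompression.

The payload byte layout (all little-endian) is documented in
``docs/format.md``; the read_id comes first precisely so that partial
decompression can stop early.
"""

from __future__ import annotations

import math
import struct
import zlib
from dataclasses import dataclass

import numpy as np
import zstandard

from .errors import (
    CorruptBlockError,
    CorruptRecordError,
    CorruptSignalError,
    FieldOverflowError,
    UnsupportedEncodingError,
)
from .model import (
    FileHeader,
    RecordCompression,
    SignalCompression,
    SignalRecord,
)

# ---------------------------------------------------------------------------
# signal layer: svb-zd


def zigzag_encode(deltas: np.ndarray) -> np.ndarray:
    """Map signed 32-bit integers to unsigned: z = (d << 1) XOR (d >> 31)."""
    d = deltas.astype(np.int32)
    return ((d.astype(np.uint32) << np.uint32(1)) ^ (d >> 31).astype(np.uint32))


def zigzag_decode(z: np.ndarray) -> np.ndarray:
    """Inverse zig-zag: d = (z >> 1) XOR -(z & 1), as signed 32-bit."""
    z = z.astype(np.uint32)
    return ((z >> np.uint32(1)) ^ (np.uint32(0) - (z & np.uint32(1)))).astype(np.int32)


def signal_encode(signal, method: SignalCompression) -> bytes:
    """Encode int16 samples with the requested signal-layer method."""
    sig = np.asarray(signal, dtype=np.int16)
    if method == SignalCompression.NONE:
        return sig.astype("<i2").tobytes()
    if method != SignalCompression.SVB_ZD:
        raise UnsupportedEncodingError(f"unknown signal method {method!r}")
    n = sig.size
    if n == 0:
        return b""
    s32 = sig.astype(np.int32)
    deltas = np.diff(s32, prepend=np.int32(0))  # d0 = s0
    z = zigzag_encode(deltas)
    lengths = (
        np.ones(n, np.uint8)
        + (z > 0xFF)
        + (z > 0xFFFF)
        + (z > 0xFFFFFF)
    ).astype(np.uint8)
    codes = lengths - 1
    n_ctrl = (n + 3) // 4
    padded = np.zeros(n_ctrl * 4, np.uint8)
    padded[:n] = codes
    g = padded.reshape(n_ctrl, 4)
    ctrl = g[:, 0] | (g[:, 1] << 2) | (g[:, 2] << 4) | (g[:, 3] << 6)
    le = z.astype("<u4").view(np.uint8).reshape(n, 4)
    mask = np.arange(4, dtype=np.uint8)[None, :] < lengths[:, None]
    return ctrl.tobytes() + le[mask].tobytes()


def signal_decode(encoded: bytes, n: int, method: SignalCompression) -> np.ndarray:
    """Exact inverse of :func:`signal_encode`; n is the sample count."""
    if method == SignalCompression.NONE:
        if len(encoded) != 2 * n:
            raise CorruptSignalError(
                f"raw signal block is {len(encoded)} bytes, expected {2 * n}"
            )
        return np.frombuffer(encoded, dtype="<i2").astype(np.int16)
    if method != SignalCompression.SVB_ZD:
        raise UnsupportedEncodingError(f"unknown signal method {method!r}")
    if n == 0:
        if encoded:
            raise CorruptSignalError("nonempty encoding for an empty signal")
        return np.empty(0, np.int16)
    n_ctrl = (n + 3) // 4
    if len(encoded) < n_ctrl:
        raise CorruptSignalError("truncated control block")
    ctrl = np.frombuffer(encoded[:n_ctrl], np.uint8)
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = ((ctrl[:, None] >> shifts[None, :]) & 3).reshape(-1)[:n]
    lengths = codes.astype(np.int64) + 1
    total = int(lengths.sum())
    data = encoded[n_ctrl:]
    if len(data) < total:
        raise CorruptSignalError(
            f"truncated data block ({len(data)} bytes, control demands {total})"
        )
    if len(data) > total:
        raise CorruptSignalError("trailing bytes after encoded signal")
    le = np.zeros((n, 4), np.uint8)
    mask = np.arange(4)[None, :] < lengths[:, None]
    le[mask] = np.frombuffer(data, np.uint8)
    z = le.reshape(-1).view("<u4").astype(np.uint32)
    deltas = zigzag_decode(z)
    samples = np.cumsum(deltas, dtype=np.int64)
    if samples.size and (samples.min() < -(2**15) or samples.max() > 2**15 - 1):
        raise CorruptSignalError("decoded sample outside int16 range")
    return samples.astype(np.int16)


# ---------------------------------------------------------------------------
# payload packing

_AUX_SCALAR_FMT = {
    "int8": "<b",
    "int16": "<h",
    "int32": "<i",
    "int64": "<q",
    "uint8": "<B",
    "uint16": "<H",
    "uint32": "<I",
    "uint64": "<Q",
    "float": "<f",
    "double": "<d",
}

# Missing-value sentinels: signed minimum / unsigned maximum / NaN / NUL.
_INT_SENTINEL = {
    "int8": -(2**7),
    "int16": -(2**15),
    "int32": -(2**31),
    "int64": -(2**63),
    "uint8": 2**8 - 1,
    "uint16": 2**16 - 1,
    "uint32": 2**32 - 1,
    "uint64": 2**64 - 1,
}
_LEN_SENTINEL = 2**64 - 1  # length prefix meaning "missing" for string/array


def _pack_aux(name: str, tag: str, value) -> bytes:
    if tag in _AUX_SCALAR_FMT:
        if tag in _INT_SENTINEL:
            if value is None:
                return struct.pack(_AUX_SCALAR_FMT[tag], _INT_SENTINEL[tag])
            value = int(value)
            if value == _INT_SENTINEL[tag]:
                raise FieldOverflowError(
                    f"aux {name!r}: value {value} collides with the missing sentinel"
                )
            try:
                return struct.pack(_AUX_SCALAR_FMT[tag], value)
            except struct.error as exc:
                raise FieldOverflowError(f"aux {name!r}: {exc}") from exc
        # float/double: NaN is the missing sentinel
        if value is None:
            return struct.pack(_AUX_SCALAR_FMT[tag], math.nan)
        return struct.pack(_AUX_SCALAR_FMT[tag], float(value))
    if tag == "char":
        if value is None:
            return b"\x00"
        b = str(value).encode("ascii")
        if len(b) != 1 or b == b"\x00":
            raise FieldOverflowError(f"aux {name!r}: char must be one non-NUL byte")
        return b
    if tag == "string":
        if value is None:
            return struct.pack("<Q", _LEN_SENTINEL)
        b = str(value).encode("utf-8")
        return struct.pack("<Q", len(b)) + b
    if tag == "int16_array":
        if value is None:
            return struct.pack("<Q", _LEN_SENTINEL)
        arr = np.asarray(value, dtype=np.int16).astype("<i2")
        return struct.pack("<Q", arr.nbytes) + arr.tobytes()
    raise UnsupportedEncodingError(f"unknown aux type tag {tag!r}")


class _Cursor:
    """Bounds-checked reader over a payload buffer."""

    def __init__(self, buf: bytes):
        self.buf = buf
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.buf):
            raise CorruptRecordError(
                f"payload truncated at byte {self.pos} (need {n} more)"
            )
        out = self.buf[self.pos : self.pos + n]
        self.pos += n
        return out

    def unpack(self, fmt: str):
        return struct.unpack(fmt, self.take(struct.calcsize(fmt)))


def _unpack_aux(cur: _Cursor, name: str, tag: str):
    if tag in _INT_SENTINEL:
        (v,) = cur.unpack(_AUX_SCALAR_FMT[tag])
        return None if v == _INT_SENTINEL[tag] else int(v)
    if tag in ("float", "double"):
        (v,) = cur.unpack(_AUX_SCALAR_FMT[tag])
        return None if math.isnan(v) else float(v)
    if tag == "char":
        b = cur.take(1)
        return None if b == b"\x00" else b.decode("ascii")
    if tag == "string":
        (length,) = cur.unpack("<Q")
        if length == _LEN_SENTINEL:
            return None
        return cur.take(length).decode("utf-8")
    if tag == "int16_array":
        (nbytes,) = cur.unpack("<Q")
        if nbytes == _LEN_SENTINEL:
            return None
        if nbytes % 2:
            raise CorruptRecordError(f"aux {name!r}: odd int16_array byte length")
        return np.frombuffer(cur.take(nbytes), dtype="<i2").astype(np.int16)
    raise UnsupportedEncodingError(f"unknown aux type tag {tag!r}")


def pack_record(
    record: SignalRecord,
    header: FileHeader,
    signal_method: SignalCompression = SignalCompression.SVB_ZD,
) -> bytes:
    """Serialize one record to its uncompressed payload bytes.

    The read_id is first so that a partially decompressed prefix suffices to
    identify the record.
    """
    id_bytes = record.read_id.encode("utf-8")
    if len(id_bytes) > 0xFFFF:
        raise FieldOverflowError(
            f"read_id is {len(id_bytes)} bytes; the layout allows at most 65535"
        )
    parts = [
        struct.pack("<H", len(id_bytes)),
        id_bytes,
        struct.pack("<I", record.read_group),
        struct.pack(
            "<dddd",
            record.digitisation,
            record.offset,
            record.range,
            record.sampling_rate,
        ),
        struct.pack("<Q", record.len_raw_signal),
    ]
    if signal_method == SignalCompression.SVB_ZD:
        enc = signal_encode(record.raw_signal, signal_method)
        parts.append(struct.pack("<Q", len(enc)))
        parts.append(enc)
    elif signal_method == SignalCompression.NONE:
        parts.append(signal_encode(record.raw_signal, signal_method))
    else:
        raise UnsupportedEncodingError(f"unknown signal method {signal_method!r}")
    for name, tag in header.aux_schema:
        parts.append(_pack_aux(name, tag, record.aux.get(name)))
    return b"".join(parts)


def unpack_record(
    payload: bytes,
    header: FileHeader,
    signal_method: SignalCompression = SignalCompression.SVB_ZD,
) -> SignalRecord:
    """Exact inverse of :func:`pack_record`; trailing bytes are an error."""
    cur = _Cursor(payload)
    (id_len,) = cur.unpack("<H")
    read_id = cur.take(id_len).decode("utf-8")
    (read_group,) = cur.unpack("<I")
    digitisation, offset, range_, sampling_rate = cur.unpack("<dddd")
    (n,) = cur.unpack("<Q")
    if signal_method == SignalCompression.SVB_ZD:
        (enc_len,) = cur.unpack("<Q")
        raw = signal_decode(cur.take(enc_len), n, signal_method)
    elif signal_method == SignalCompression.NONE:
        raw = signal_decode(cur.take(2 * n), n, signal_method)
    else:
        raise UnsupportedEncodingError(f"unknown signal method {signal_method!r}")
    aux = {}
    for name, tag in header.aux_schema:
        aux[name] = _unpack_aux(cur, name, tag)
    if cur.pos != len(payload):
        raise CorruptRecordError(
            f"{len(payload) - cur.pos} trailing bytes after record payload"
        )
    return SignalRecord(
        read_id=read_id,
        read_group=read_group,
        digitisation=digitisation,
        offset=offset,
        range=range_,
        sampling_rate=sampling_rate,
        raw_signal=raw,
        len_raw_signal=n,
        aux=aux,
    )


# ---------------------------------------------------------------------------
# record layer: block compression


def compress_block(data: bytes, method: RecordCompression) -> bytes:
    if method == RecordCompression.NONE:
        return data
    if method == RecordCompression.ZLIB:
        return zlib.compress(data)
    if method == RecordCompression.ZSTD:
        return zstandard.compress(data)
    raise UnsupportedEncodingError(f"unknown record method {method!r}")


def decompress_block(data: bytes, method: RecordCompression) -> bytes:
    if method == RecordCompression.NONE:
        return data
    try:
        if method == RecordCompression.ZLIB:
            return zlib.decompress(data)
        if method == RecordCompression.ZSTD:
            return zstandard.decompress(data)
    except (zlib.error, zstandard.ZstdError) as exc:
        raise CorruptBlockError(f"corrupt {method.value} block: {exc}") from exc
    raise UnsupportedEncodingError(f"unknown record method {method!r}")


# ---------------------------------------------------------------------------
# partial decompression of the record prefix


@dataclass(frozen=True)
class PeekResult:
    read_id: str
    read_group: int | None
    bytes_produced: int  # decompressed bytes materialized to obtain the result


class _PartialInflater:
    """Incremental zlib reader that produces only as many bytes as asked."""

    def __init__(self, data: bytes):
        self._obj = zlib.decompressobj()
        self._pending = data
        self.produced = 0

    def read(self, n: int) -> bytes:
        out = b""
        while len(out) < n:
            if not self._pending:
                raise CorruptRecordError("compressed stream ended before read_id")
            try:
                chunk = self._obj.decompress(self._pending, n - len(out))
            except zlib.error as exc:
                raise CorruptRecordError(f"corrupt zlib stream: {exc}") from exc
            self._pending = self._obj.unconsumed_tail
            if not chunk and not self._pending:
                raise CorruptRecordError("compressed stream ended before read_id")
            out += chunk
        self.produced += len(out)
        return out


def peek_record_prefix(
    compressed: bytes,
    method: RecordCompression,
    include_group: bool = False,
) -> PeekResult:
    """Extract the read_id (and optionally read_group) from a compressed payload.

    Under zlib (and the identity method) only the needed prefix is
    decompressed; zstd does not support partial decompression, so the whole
    payload is decompressed first.
    """
    if method == RecordCompression.ZLIB:
        inf = _PartialInflater(compressed)
        (id_len,) = struct.unpack("<H", inf.read(2))
        read_id = inf.read(id_len).decode("utf-8")
        group = None
        if include_group:
            (group,) = struct.unpack("<I", inf.read(4))
        return PeekResult(read_id, group, inf.produced)
    if method in (RecordCompression.NONE, RecordCompression.ZSTD):
        payload = decompress_block(compressed, method)
        cur = _Cursor(payload)
        try:
            (id_len,) = cur.unpack("<H")
            read_id = cur.take(id_len).decode("utf-8")
            group = cur.unpack("<I")[0] if include_group else None
        except CorruptRecordError:
            raise
        produced = cur.pos if method == RecordCompression.NONE else len(payload)
        return PeekResult(read_id, group, produced)
    raise UnsupportedEncodingError(f"unknown record method {method!r}")


def peek_read_id(compressed: bytes, method: RecordCompression) -> str:
    """The read_id of a compressed payload, via partial decompression."""
    return peek_record_prefix(compressed, method).read_id
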