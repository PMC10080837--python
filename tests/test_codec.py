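"""Codec tests, anchored on an independent scalar reference implementation
of each svb-zd stage (delta, zig-zag, stream-variable-byte)."""

import struct

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slow5kit import codec
from slow5kit.errors import (
    CorruptBlockError,
    CorruptRecordError,
    CorruptSignalError,
    FieldOverflowError,
    UnsupportedEncodingError,
)
from slow5kit.fast5_bridge import AUX_SCHEMA
from slow5kit.model import (
    FileHeader,
    RecordCompression,
    SignalCompression,
    SignalRecord,
)

# ---------------------------------------------------------------------------
# scalar reference oracle (pure-Python, no numpy), independent of the codec


def ref_svb_zd_encode(samples):
    deltas, prev = [], 0
    for s in samples:
        deltas.append(s - prev)
        prev = s
    zz = []
    for d in deltas:
        d &= 0xFFFFFFFF  # two's complement 32-bit
        if d >= 2**31:
            d -= 2**32
        zz.append(((d << 1) ^ (d >> 31)) & 0xFFFFFFFF)
    ctrl = bytearray((len(zz) + 3) // 4)
    data = bytearray()
    for i, z in enumerate(zz):
        nbytes = 1 if z < 2**8 else 2 if z < 2**16 else 3 if z < 2**24 else 4
        ctrl[i // 4] |= (nbytes - 1) << (2 * (i % 4))
        data += z.to_bytes(nbytes, "little")
    return bytes(ctrl) + bytes(data) if samples else b""


@pytest.mark.parametrize(
    "samples,expected",
    [
        ([], b""),
        ([5, 5, 5], bytes([0b00000000, 0x0A, 0x00, 0x00])),
        ([-1], bytes([0b00000000, 0x01])),
        ([0, 300], bytes([0b00000100, 0x00, 0x58, 0x02])),
    ],
)
def test_svb_zd_frozen_examples(samples, expected):
    assert ref_svb_zd_encode(samples) == expected  # oracle agrees
    assert codec.signal_encode(samples, SignalCompression.SVB_ZD) == expected


@given(
    st.lists(st.integers(-(2**15), 2**15 - 1), min_size=0, max_size=300),
)
@settings(max_examples=300, deadline=None)
def test_encode_matches_scalar_reference_and_inverts(samples):
    arr = np.array(samples, np.int16)
    enc = codec.signal_encode(arr, SignalCompression.SVB_ZD)
    assert enc == ref_svb_zd_encode(samples)
    dec = codec.signal_decode(enc, len(samples), SignalCompression.SVB_ZD)
    assert np.array_equal(dec, arr)


def test_roundtrip_at_int16_extremes():
    x = np.array([-32768, 32767, 0], np.int16)
    enc = codec.signal_encode(x, SignalCompression.SVB_ZD)
    assert np.array_equal(
        codec.signal_decode(enc, 3, SignalCompression.SVB_ZD), x
    )


def test_zigzag_bijection_exhaustive():
    d = np.arange(-1000, 1001, dtype=np.int32)
    z = codec.zigzag_encode(d)
    assert len(set(z.tolist())) == d.size  # injective on the range
    assert np.array_equal(codec.zigzag_decode(z), d)
    # small magnitudes get small codes
    assert codec.zigzag_encode(np.array([0], np.int32))[0] == 0
    assert codec.zigzag_encode(np.array([-1], np.int32))[0] == 1
    assert codec.zigzag_encode(np.array([1], np.int32))[0] == 2


def test_one_byte_delta_size_formula():
    # deltas of magnitude <= 127 all fit one byte: size == ceil(n/4) + n
    for n in (1, 4, 5, 17, 100):
        sig = np.cumsum(np.full(n, 3, np.int64)).astype(np.int16)
        enc = codec.signal_encode(sig, SignalCompression.SVB_ZD)
        assert len(enc) == (n + 3) // 4 + n


def test_decode_truncated_raises():
    with pytest.raises(CorruptSignalError):
        codec.signal_decode(b"\x00", 4, SignalCompression.SVB_ZD)


def test_decode_trailing_bytes_raises():
    enc = codec.signal_encode([1, 2], SignalCompression.SVB_ZD)
    with pytest.raises(CorruptSignalError):
        codec.signal_decode(enc + b"\x00", 2, SignalCompression.SVB_ZD)


def test_decode_empty():
    out = codec.signal_decode(b"", 0, SignalCompression.SVB_ZD)
    assert out.size == 0


def test_unknown_method_rejected():
    with pytest.raises(UnsupportedEncodingError):
        codec.signal_encode([1], "brotli")


def test_raw_encoding_is_little_endian_int16():
    enc = codec.signal_encode([1, -2], SignalCompression.NONE)
    assert enc == b"\x01\x00\xfe\xff"


# ---------------------------------------------------------------------------
# record packing


HEADER = FileHeader(aux_schema=AUX_SCHEMA)


def make_record(i=0, rng=None):
    rng = rng or np.random.default_rng(i)
    return SignalRecord(
        read_id=f"read-{i:06d}",
        read_group=0,
        digitisation=8192.0,
        offset=float(rng.integers(-10, 10)),
        range=1402.882,
        sampling_rate=4000.0,
        raw_signal=rng.integers(-1000, 1000, int(rng.integers(0, 200))).astype(
            np.int16
        ),
        aux={
            "channel_number": str(int(rng.integers(1, 513))),
            "median_before": float(rng.normal(220, 20)),
            "read_number": i,
            "start_mux": int(rng.integers(1, 5)),
            "start_time": int(rng.integers(0, 10**12)),
        },
    )


def test_payload_begins_with_read_id_length_and_bytes():
    rec = SignalRecord(read_id="r1", aux={n: None for n, _ in AUX_SCHEMA})
    payload = codec.pack_record(rec, HEADER)
    assert payload[:4] == b"\x02\x00r1"


def test_read_group_occupies_four_bytes_after_read_id():
    base = {n: None for n, _ in AUX_SCHEMA}
    a = SignalRecord(read_id="rx", read_group=0, aux=dict(base))
    b = SignalRecord(read_id="rx", read_group=7, aux=dict(base))
    pa = codec.pack_record(a, FileHeader(num_read_groups=8, aux_schema=AUX_SCHEMA))
    pb = codec.pack_record(b, FileHeader(num_read_groups=8, aux_schema=AUX_SCHEMA))
    assert len(pa) == len(pb)
    diff = [i for i in range(len(pa)) if pa[i] != pb[i]]
    assert diff and all(4 <= i < 8 for i in diff)


def test_pack_unpack_roundtrip_random_records():
    rng = np.random.default_rng(42)
    for i in range(300):
        rec = make_record(i, rng)
        payload = codec.pack_record(rec, HEADER)
        assert codec.unpack_record(payload, HEADER) == rec


def test_roundtrip_with_all_aux_types_populated():
    schema = tuple((f"f_{t}", t) for t in (
        "int8", "int16", "int32", "int64", "uint8", "uint16", "uint32",
        "uint64", "float", "double", "char", "string", "int16_array",
    ))
    header = FileHeader(aux_schema=schema)
    aux = {
        "f_int8": -5, "f_int16": -1000, "f_int32": 2**30, "f_int64": -(2**40),
        "f_uint8": 200, "f_uint16": 60000, "f_uint32": 2**31, "f_uint64": 2**60,
        "f_float": 1.5, "f_double": 3.141592653589793, "f_char": "A",
        "f_string": "hello world", "f_int16_array": np.array([1, -2, 3], np.int16),
    }
    rec = SignalRecord(read_id="maximal", raw_signal=np.array([9], np.int16), aux=aux)
    assert codec.unpack_record(codec.pack_record(rec, header), header) == rec
    # and with every value missing
    rec2 = SignalRecord(read_id="all-missing", aux={k: None for k in aux})
    assert codec.unpack_record(codec.pack_record(rec2, header), header) == rec2


def test_truncated_payload_raises():
    payload = codec.pack_record(make_record(1), HEADER)
    with pytest.raises(CorruptRecordError):
        codec.unpack_record(payload[: len(payload) // 2], HEADER)


def test_trailing_bytes_raise():
    payload = codec.pack_record(make_record(2), HEADER)
    with pytest.raises(CorruptRecordError):
        codec.unpack_record(payload + b"\x00\x00\x00", HEADER)


def test_oversized_read_id_rejected():
    rec = SignalRecord(read_id="x" * 70000, aux={n: None for n, _ in AUX_SCHEMA})
    with pytest.raises(FieldOverflowError):
        codec.pack_record(rec, HEADER)


# ---------------------------------------------------------------------------
# block compression


@pytest.mark.parametrize("method", list(RecordCompression))
def test_block_roundtrip(method):
    rng = np.random.default_rng(3)
    for size in (0, 1, 1000):
        data = rng.integers(0, 256, size).astype(np.uint8).tobytes()
        out = codec.decompress_block(codec.compress_block(data, method), method)
        assert out == data


def test_none_compression_is_identity():
    assert codec.compress_block(b"abc", RecordCompression.NONE) == b"abc"


@pytest.mark.parametrize(
    "method", [RecordCompression.ZLIB, RecordCompression.ZSTD]
)
def test_random_bytes_are_corrupt_blocks(method):
    with pytest.raises(CorruptBlockError):
        codec.decompress_block(b"\x01\x02\x03\x04not-a-stream", method)


# ---------------------------------------------------------------------------
# partial decompression


@pytest.mark.parametrize("method", list(RecordCompression))
def test_peek_read_id_matches_full_parse(method):
    rng = np.random.default_rng(8)
    for i in range(100):
        rec = make_record(i, rng)
        payload = codec.pack_record(rec, HEADER)
        compressed = codec.compress_block(payload, method)
        assert codec.peek_read_id(compressed, method) == rec.read_id


def test_zlib_peek_is_genuinely_partial():
    # a long signal: the peek must materialize only the read_id prefix,
    # not the whole payload
    rng = np.random.default_rng(9)
    rec = make_record(0, rng)
    rec.raw_signal = rng.integers(-500, 500, 500_000).astype(np.int16)
    rec.len_raw_signal = 500_000
    payload = codec.pack_record(rec, HEADER)
    compressed = codec.compress_block(payload, RecordCompression.ZLIB)
    peek = codec.peek_record_prefix(compressed, RecordCompression.ZLIB)
    assert peek.read_id == rec.read_id
    assert peek.bytes_produced == 2 + len(rec.read_id)
    assert peek.bytes_produced < len(payload) // 100


def test_peek_includes_read_group_when_asked():
    header = FileHeader(num_read_groups=5, aux_schema=AUX_SCHEMA)
    rec = make_record(3)
    rec.read_group = 4
    payload = codec.pack_record(rec, header)
    compressed = codec.compress_block(payload, RecordCompression.ZLIB)
    peek = codec.peek_record_prefix(
        compressed, RecordCompression.ZLIB, include_group=True
    )
    assert (peek.read_id, peek.read_group) == (rec.read_id, 4)


def test_peek_on_corrupt_zlib_stream_raises():
    with pytest.raises(CorruptRecordError):
        codec.peek_read_id(b"\x00\x01garbage", RecordCompression.ZLIB)
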