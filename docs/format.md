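# Byte layouts (normative for slow5kit)

All integers are little-endian. These layouts are self-consistent and
documented here so every test is deterministic; byte-level interoperability
with other SLOW5 implementations is not claimed.

## SLOW5 ASCII (.slow5)

UTF-8 text, `\n` line endings (`\r\n` tolerated on read), tab-separated:

```
#slow5_version<TAB>0.1.0
#num_read_groups<TAB>N
@<attribute><TAB><value for group 0><TAB><value for group 1>...
...                       (one line per attribute, lexicographic key order)
#string<TAB>uint32<TAB>double<TAB>double<TAB>double<TAB>double<TAB>uint64<TAB>int16_array[<TAB>aux types...]
#read_id<TAB>read_group<TAB>digitisation<TAB>offset<TAB>range<TAB>sampling_rate<TAB>len_raw_signal<TAB>raw_signal[<TAB>aux names...]
<one row per record>
```

Arrays are comma-separated integers; floats use shortest round-trip
decimals; a missing auxiliary value is `.`. An empty signal is an empty
field. A `char` or `string` aux value equal to `.` is indistinguishable
from missing in this form (binary form unaffected).

## BLOW5 container (.blow5)

```
offset  size  field
0       8     magic = 8A 42 4C 4F 57 35 0D 0A   ("\x8aBLOW5\r\n")
8       1     record-layer method: 0=none 1=zlib 2=zstd
9       1     signal-layer method: 0=none 1=svb-zd
10      4     header_length (uint32)
14      L     header block: the SLOW5 ASCII header text, uncompressed
14+L    ...   record frames
end-8   8     EOF marker = 8A 35 45 4F 46 0D 0A 00   ("\x8a5EOF\r\n\x00")
```

Each record frame is `uint32 frame_length` followed by exactly
`frame_length` bytes of record-layer-compressed payload. A file whose last
8 bytes are not the EOF marker, or whose final frame crosses the marker, is
truncated.

## Record payload (before record-layer compression)

```
uint16  read_id byte length        (read_id first: partial decompression
bytes   read_id (UTF-8)             needs only this prefix)
uint32  read_group
float64 digitisation
float64 offset
float64 range
float64 sampling_rate
uint64  len_raw_signal             (sample count)
signal:
  svb-zd: uint64 encoded byte length, then encoded bytes
  none:   len_raw_signal * 2 bytes of little-endian int16 samples
aux values, in schema order (see below)
```

Trailing bytes after the last aux value are a parse error.

### svb-zd signal encoding

1. Widen each int16 sample to int32 (so deltas at the extremes cannot
   overflow).
2. Delta: `d0 = s0`, `di = si − si−1`.
3. Zig-zag to uint32: `z = (d << 1) XOR (d >> 31)` (arithmetic shift).
4. Stream variable byte: `ceil(n/4)` control bytes, then data bytes.
   Value *i*'s 2-bit field sits at bits `2*(i mod 4)..2*(i mod 4)+1`
   (low bits first) of control byte `i div 4` and encodes
   (byte length − 1) ∈ {0,1,2,3}; each value is little-endian in its
   declared length. An empty signal encodes to zero bytes.

### Auxiliary value encoding and missing sentinels

| type tag     | encoding                   | missing sentinel            |
|--------------|----------------------------|-----------------------------|
| int8..int64  | signed LE scalar           | the type's minimum value    |
| uint8..uint64| unsigned LE scalar         | the type's maximum value    |
| float,double | IEEE-754 LE                | NaN                         |
| char         | 1 byte ASCII               | 0x00                        |
| string       | uint64 length + UTF-8 bytes| length = 2^64 − 1           |
| int16_array  | uint64 byte length + LE samples | length = 2^64 − 1      |

A real value equal to its sentinel cannot be stored and is rejected at
pack time. NaN float aux values are therefore representable only as
missing.

## Index sidecar (.idx)

```
8 bytes   magic "SLOW5IDX"
uint64    source data file size at build time (staleness check)
uint64    entry count
entries:  uint16 read_id length | read_id bytes | uint64 offset | uint64 length
```

For BLOW5, `offset` addresses the frame's length prefix and `length` is
the full frame length (prefix included); for ASCII SLOW5, `offset` is the
record line's start and `length` the line length including its newline.
Entries appear in file order.
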