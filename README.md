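# slow5kit

SLOW5/BLOW5 file formats and a dataset toolkit for nanopore raw signal data.

Oxford Nanopore sequencers measure ionic current through a pore as a time
series of signed 16-bit ADC samples. The vendor's FAST5 container (HDF5)
stores these reads, but HDF5's single-threaded core library makes parallel
signal-level analysis I/O-bound. SLOW5 is a simple alternative: a
tab-separated ASCII form for inspection, and a compressed binary form
(BLOW5) for real work, with a sidecar index for single-seek random access
by read identifier. `slow5kit` implements both forms, lossless FAST5
conversion in both directions, and the surrounding dataset operations
(merge, cat, split, get, view, stats, quickcheck, skim, live conversion).
It is aimed at people building signal-level tools — base callers,
methylation callers, selective-sequencing pipelines — and at anyone
managing sequencing-run archives.

## The data model

A record holds one read: a `read_id`, a `read_group` (index into per-run
metadata tables in the file header), four calibration scalars, and the raw
signal. Calibration converts ADC counts to picoamperes:

    pA_i = (raw_i + offset) * range / digitisation

Auxiliary per-read attributes (channel number, start time, ...) follow a
typed schema declared in the header, with an explicit missing marker for
every type.

BLOW5 applies two independent compression layers:

* **signal layer** (`svb-zd`): widen samples to 32 bits, delta-code
  (`d0 = s0`, `di = si − si−1`), zig-zag map `z = (d << 1) XOR (d >> 31)`,
  then stream-variable-byte pack (2-bit length codes in control bytes,
  little-endian data bytes). Pore signals dwell at near-constant levels, so
  deltas are small and most samples shrink to one byte.
* **record layer**: the whole packed record is compressed with zlib
  (default) or zstd, or stored as is. zlib supports partial decompression,
  which indexing uses to extract only the leading `read_id`; zstd does not,
  and falls back to full decompression.

All six (record, signal) combinations are legal and lossless. The byte
layouts of the container, the record payload, and the index sidecar are
specified in [`docs/format.md`](docs/format.md); the model and design
choices are discussed in [`docs/methods.md`](docs/methods.md).

## Worked example

Generate a small synthetic run, convert it, and poke at the result:

```sh
$ slow5kit simulate --seed 42 --n-reads 50 --out-dir f5 --format fast5
[slow5kit] INFO: wrote 1 FAST5 files

$ slow5kit f2s f5 -d blow5
[slow5kit] INFO: f5/run00000042g0_0000.fast5: 50 reads -> blow5/run00000042g0_0000.blow5

$ slow5kit stats blow5/run00000042g0_0000.blow5
records	50
read_groups	1
compression	zlib,svb-zd
primary_fields	read_id,read_group,digitisation,offset,range,sampling_rate,len_raw_signal,raw_signal
aux_fields	channel_number:string,median_before:double,read_number:int32,start_mux:uint8,start_time:uint64
group_0_records	50

$ slow5kit index blow5/run00000042g0_0000.blow5
[slow5kit] INFO: wrote blow5/run00000042g0_0000.blow5.idx

$ slow5kit skim blow5/run00000042g0_0000.blow5 --read-ids | head -3
318fbcbc-82d7-852e-ca6d-877318e1dd4a
cd33e874-ac08-f44e-067c-262ca762ea56
404e2b08-e539-4eda-a9b7-f50baf6686c6

$ slow5kit view blow5/run00000042g0_0000.blow5 | head -3
#slow5_version	0.1.0
#num_read_groups	1
@device_id	MN12345
```

The stats output reads: 50 records in one read group, compressed with the
default `[zlib, svb-zd]` spec, carrying the five standard auxiliary fields.
`slow5kit get FILE READ_ID...` then fetches records in request order with
one seek each; `merge`/`cat`/`split` reorganize datasets while conserving
every record; `slow5kit watch RUN_DIR -d OUT` live-converts FAST5 files as
a sequencer drops them.

The same operations are available as a library:

```python
from slow5kit import SyntheticConfig, generate_records, write_blow5, read_blow5_all

header, records = generate_records(SyntheticConfig(seed=42, n_reads=50))
write_blow5(header, records, "demo.blow5")
header2, records2 = read_blow5_all("demo.blow5")
assert records2 == records   # lossless
```

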