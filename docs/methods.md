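# Methods

## The model

A nanopore read is a sequence of signed 16-bit ADC samples plus calibration
scalars (`digitisation`, `offset`, `range`, `sampling_rate`) converting
counts to picoamperes, `pA = (raw + offset) * range / digitisation`, and
samples to time. Reads sharing acquisition metadata form a *read group*;
the file header stores one attribute map per group and a typed schema for
per-read auxiliary attributes. `slow5kit` treats the record, not the file,
as the unit of work: every dataset operation is defined by what it does to
an ordered stream of records, and every operation is required to be a
deterministic function of its input order. That single contract is what
makes the parallelism guarantees testable — a command run twice, or with
any worker count, must produce byte-identical output.

## Compression

Two independent layers. The signal layer (`svb-zd`) exploits the physics:
current dwells at a near-constant level while one k-mer occupies the pore,
so consecutive deltas are small. Delta coding, zig-zag mapping (small
magnitudes → small codes) and stream-variable-byte packing store most
samples in one byte plus a quarter byte of control. The record layer then
compresses the whole packed payload with zlib (default) or zstd. zlib was
kept as the default for the same reason it is ubiquitous: universal
availability; zstd is more compact and faster where available.

Choices fixed here because they are genuinely open:

* svb-zd operates on 32-bit widened values — an int16 delta spans up to
  65,535, which does not fit the source width. The first delta is the first
  sample itself, keeping a single uniform stream.
* Control-byte bit order is low-bits-first (value *i* at bits
  `2*(i mod 4)`); some stream-variable-byte variants pack high-first.
  One order had to be fixed for determinism.
* Codec levels are the library defaults and are not persisted: both zlib
  and zstd decompression are level-agnostic.
* The missing-value sentinels (type minimum / maximum / NaN / NUL /
  all-ones length) make missingness representable for every auxiliary type
  without a presence byte; the cost is that those exact values are
  unstorable, which no real acquisition produces.

## Partial decompression

Indexing needs only each record's `read_id`. The payload puts the read_id
first precisely so a zlib stream can be inflated incrementally and stopped
after `2 + len(read_id)` output bytes; the implementation caps the inflater's
output, so the work done is proportional to the prefix, not the record.
zstd frames cannot be partially decompressed, so the zstd path inflates the
whole payload first. The two paths must — and are tested to — produce
byte-identical index files; the choice changes speed, never results.
`stats` reuses the same mechanism to reach `read_group` (4 more bytes)
without parsing signals, and linear passes read through a 128 KiB buffer.

## Dataset operations

* **merge** unifies read groups on full attribute-map equality — the only
  metadata-driven identity test that needs no configuration. New groups are
  numbered in first-encounter order over inputs in argument order
  (directories expanded lexicographically). Duplicate read_ids are *not*
  rejected at merge time (a streaming writer cannot check globally);
  they surface at index construction. If inputs' attribute key sets differ,
  the merged header takes the union with empty strings for absent values,
  so the per-group key-set invariant holds without dropping records.
* **cat** refuses anything but byte-identical header blocks and
  compression specs, then splices raw frame regions without decompressing.
  This is the fast path for re-joining MinKNOW-style batches; merge is the
  general tool.
* **split** offers by-group, reads-per-file, and file-count modes; the
  chunk modes require a single-group input (otherwise group membership and
  contiguity conflict). File-count chunks differ in size by at most one,
  larger first; outputs are `<stem>_<ordinal, zero-padded to 4><suffix>`.
* **get** preserves request order (duplicates included), builds a missing
  or stale index automatically, and with `--skip` counts absent ids
  instead of failing.
* **quickcheck** verifies magic, header parse, EOF marker, and the first
  frame — structural integrity in O(1) record reads, not a full scan.

Parallelism is a contract, not a mechanism: directory conversion
partitions the file list as evenly as possible (sizes differ by ≤1,
larger chunks first) across a thread pool, but since outputs are
per-file-independent and the manifest is sorted by input path, results are
independent of the worker count by construction.

## FAST5 bridge

Multi-read FAST5 only (one HDF5 group `read_<id>` per read, signal at
`Raw/Signal`, calibration under `channel_id`, run metadata under
`tracking_id`/`context_tags`). Legacy single-read files are a documented
extension point, not implemented — their layout varies too much to promise
losslessness. `f2s` makes each FAST5 file one read group; `s2f` re-batches
at 4000 reads per file (the MinKNOW default) and never mixes groups in a
file. Auxiliary fields with no defined FAST5 home are written under a
reserved `slow5_extra` group with a warning, never dropped. Written FAST5
files use HDF5 creation-order tracking so read order round-trips.

The live watcher polls the run directory (default every 5 s) instead of
using kernel file notification; the contract is detection + FIFO queueing
with a bounded number of in-flight conversions, not the mechanism. A file
counts as complete when its size is unchanged across two polls — polling
needs an explicit completeness rule where an acquisition daemon would close
files. With deletion enabled, a source FAST5 is removed only after the
output passes quickcheck and its record count matches the input's read
count.

## Synthetic data

The generator is the single source of ground truth in tests. Its signal
model is a random walk with segment-wise level shifts (mean dwell ~40
samples, level-shift scale 60 ADC counts, within-segment step scale 3),
around a 500-count baseline with MinION-like calibration constants
(digitisation 8192, range ≈1402.9 pA, 4 kHz sampling). This emulates the
feature that matters to the codec — small deltas punctuated by jumps; pure
white noise would make delta coding pointless and constants would make it
trivial. Reads are batched 4000 per FAST5 file as MinKNOW does; auxiliary
fields carry occasional missing values (rate 0.05) because real runs omit
fields per read. Everything derives deterministically from the seed.

What the generator does **not** emulate: base-caller-meaningful k-mer
sequence structure, channel-correlated noise, adapter/stall artefacts, or
multi-run FAST5 directories. Passing tests therefore demonstrate format
correctness, losslessness and the operational contracts — not base-calling
fidelity or performance on any real dataset.

## Problem sizes and numerical choices

Round-trip and random-access checks run at 1,000 records (signals 100–1,500
samples), codec fuzzing at 10,000 arrays, the FAST5 round trip at 9,000
reads across three files, split arithmetic at 10,000 records — sizes chosen
so the full verification pipeline completes in about a minute while still
exercising multi-file batching, multi-byte svb codes and every edge case
(empty signals, int16 extremes, all-missing auxiliary rows, long read_ids).
Floats round-trip through ASCII via shortest-repr decimals; record frames
cap at 4 GiB (uint32 length), read_ids at 65,535 bytes. Truncation
detection relies on the EOF marker plus exact frame accounting; index
staleness on recorded file size, not modification times.

## Known limitations

* No gzip-compressed ASCII SLOW5, memory-mapped access, positional (nth
  record) queries, or range queries.
* `char`/`string` auxiliary values equal to `"."` are ambiguous with the
  missing token in the ASCII form only.
* Byte compatibility with files produced by other SLOW5 implementations is
  out of scope; the layouts in `docs/format.md` are normative for this
  package alone.
* VBZ-plugin-compressed FAST5 signal datasets and bulk/playback FAST5
  files are unsupported.
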