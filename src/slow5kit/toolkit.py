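"""Dataset-level operations: merge, cat, split, get, view, stats, quickcheck, skim.

All operations are deterministic functions of their input order: rerunning a
command, or running it with a different worker count, yields byte-identical
output. Formats are detected by content (BLOW5 magic) with the file
extension as a tie-break for outputs.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass, field
from pathlib import Path

from . import codec
from .ascii_format import header_text, read_slow5, write_slow5
from .blow5_format import (
    EOF_MARKER,
    MAGIC,
    Blow5Reader,
    decode_frame,
    write_blow5,
)
from .errors import (
    MetadataMismatchError,
    ReadIdNotFoundError,
    SchemaConflictError,
    Slow5Error,
)
from .index import RandomAccessor, build_index, default_index_path, load_index
from .model import (
    CompressionSpec,
    DEFAULT_SPEC,
    FileHeader,
    PRIMARY_COLUMNS,
    SignalRecord,
)

BLOW5_SUFFIX = ".blow5"
SLOW5_SUFFIX = ".slow5"


def is_blow5_path(path) -> bool:
    path = Path(path)
    if not path.exists():
        return path.suffix == BLOW5_SUFFIX
    with open(path, "rb") as fh:
        return fh.read(8) == MAGIC


def read_any(path) -> tuple[FileHeader, Iterator[SignalRecord]]:
    """Open a SLOW5 or BLOW5 file; returns (header, lazy record stream)."""
    if is_blow5_path(path):
        from .blow5_format import open_blow5

        return open_blow5(path)
    return read_slow5(path)


def write_any(
    path, header: FileHeader, records: Iterable[SignalRecord],
    spec: CompressionSpec = DEFAULT_SPEC,
) -> int:
    """Write records to SLOW5 or BLOW5 depending on the path's extension."""
    if Path(path).suffix == SLOW5_SUFFIX:
        return write_slow5(header, records, path)
    return write_blow5(header, records, path, spec)


def _expand_inputs(inputs: Sequence) -> list[Path]:
    """Expand directories (recursively, lexicographic) into file lists."""
    out: list[Path] = []
    for item in inputs:
        p = Path(item)
        if p.is_dir():
            out.extend(
                sorted(
                    q
                    for q in p.rglob("*")
                    if q.is_file() and q.suffix in (BLOW5_SUFFIX, SLOW5_SUFFIX)
                )
            )
        else:
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# merge


@dataclass
class MergePlan:
    """How source read groups map into the merged file.

    ``group_map[(input_index, source_group)]`` is the target group index.
    Source groups with identical attribute maps are unified; new groups are
    numbered in first-encounter order over the inputs.
    """

    group_map: dict[tuple[int, int], int] = field(default_factory=dict)
    group_attributes: list[dict[str, str]] = field(default_factory=list)


def plan_merge(headers: Sequence[FileHeader]) -> MergePlan:
    schema = headers[0].aux_schema
    for i, h in enumerate(headers[1:], 1):
        if h.aux_schema != schema:
            raise SchemaConflictError(
                f"input {i} has aux schema {h.aux_schema}, "
                f"input 0 has {schema}"
            )
    plan = MergePlan()
    seen: dict[tuple, int] = {}
    for i, h in enumerate(headers):
        for g, attrs in enumerate(h.group_attributes):
            key = tuple(sorted(attrs.items()))
            if key not in seen:
                seen[key] = len(plan.group_attributes)
                plan.group_attributes.append(dict(attrs))
            plan.group_map[(i, g)] = seen[key]
    # headers must share one key set across groups; absent keys become ""
    all_keys = sorted({k for g in plan.group_attributes for k in g})
    for g in plan.group_attributes:
        for k in all_keys:
            g.setdefault(k, "")
    return plan


def merge(
    inputs: Sequence,
    output,
    spec: CompressionSpec = DEFAULT_SPEC,
) -> tuple[int, MergePlan]:
    """Merge SLOW5/BLOW5 files into one, re-tagging read groups.

    Each distinct source attribute map becomes one output read group; within
    each input, record order is preserved. Inputs are processed in argument
    order, directories expanded in lexicographic filename order.
    """
    paths = _expand_inputs(inputs)
    if not paths:
        raise Slow5Error("merge needs at least one input")
    headers = []
    for p in paths:
        h, stream = read_any(p)
        # drain nothing; reopen for the record pass below
        headers.append(h)
    plan = plan_merge(headers)
    merged_header = FileHeader(
        num_read_groups=len(plan.group_attributes),
        group_attributes=plan.group_attributes,
        aux_schema=headers[0].aux_schema,
    )

    def stream() -> Iterator[SignalRecord]:
        for i, p in enumerate(paths):
            _, records = read_any(p)
            for rec in records:
                rec.read_group = plan.group_map[(i, rec.read_group)]
                yield rec

    count = write_any(output, merged_header, stream(), spec)
    return count, plan


# ---------------------------------------------------------------------------
# cat


def cat(inputs: Sequence, output) -> int:
    """Concatenate BLOW5 files with byte-identical headers and specs.

    Record frames are copied verbatim (no per-record decompression); the
    result's record stream equals the inputs' streams concatenated in
    argument order. Any header or compression mismatch refuses before
    writing anything.
    """
    paths = _expand_inputs(inputs)
    if not paths:
        raise Slow5Error("cat needs at least one input")
    readers = [Blow5Reader(p) for p in paths]
    try:
        first = readers[0]
        for p, r in zip(paths[1:], readers[1:]):
            if r.header_block != first.header_block or r.spec != first.spec:
                raise MetadataMismatchError(
                    f"{p} header/compression differs from {paths[0]}; "
                    "cat combines only files with identical metadata "
                    "(use merge to assign read groups)"
                )
        count = 0
        with open(output, "wb") as out:
            with open(paths[0], "rb") as fh:
                out.write(fh.read(first.header_end))
            for p, r in zip(paths, readers):
                for _ in r.frames():
                    count += 1
                with open(p, "rb") as fh:
                    fh.seek(r.header_end)
                    remaining = r.data_end - r.header_end
                    while remaining:
                        chunk = fh.read(min(remaining, 1 << 20))
                        out.write(chunk)
                        remaining -= len(chunk)
            out.write(EOF_MARKER)
        return count
    finally:
        for r in readers:
            r.close()


# ---------------------------------------------------------------------------
# split


@dataclass(frozen=True)
class SplitSpec:
    mode: str  # by_group | reads_per_file | file_count
    parameter: int = 0  # unused for by_group

    def __post_init__(self):
        if self.mode not in ("by_group", "reads_per_file", "file_count"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode != "by_group" and self.parameter < 1:
            raise ValueError(f"{self.mode} needs a positive parameter")


def _chunk_sizes(total: int, spec: SplitSpec) -> list[int]:
    if spec.mode == "reads_per_file":
        r = spec.parameter
        sizes = [r] * (total // r)
        if total % r:
            sizes.append(total % r)
        return sizes or [0]
    # file_count: sizes differ by at most 1, larger chunks first
    f = spec.parameter
    if f > total:
        raise Slow5Error(f"cannot split {total} records into {f} files")
    base, extra = divmod(total, f)
    return [base + 1] * extra + [base] * (f - extra)


def split(
    input_path, output_dir, spec: SplitSpec,
    compression: CompressionSpec | None = None,
) -> list[tuple[Path, int]]:
    """Split one file into several; returns [(output path, record count)].

    by_group emits one single-group file per read group; the other modes
    require a single-group input and cut contiguous chunks. Output names
    are ``<input stem>_<zero-padded ordinal><input suffix>``.
    """
    input_path = Path(input_path)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    header, stream = read_any(input_path)
    if compression is None:
        compression = header.compression or DEFAULT_SPEC
    records = list(stream)
    suffix = BLOW5_SUFFIX if is_blow5_path(input_path) else SLOW5_SUFFIX
    stem = input_path.stem

    def out_path(ordinal: int) -> Path:
        return output_dir / f"{stem}_{ordinal:04d}{suffix}"

    results: list[tuple[Path, int]] = []
    if spec.mode == "by_group":
        for g in range(header.num_read_groups):
            sub_header = FileHeader(
                version=header.version,
                num_read_groups=1,
                group_attributes=[dict(header.group_attributes[g])],
                aux_schema=header.aux_schema,
            )
            subset = []
            for rec in records:
                if rec.read_group == g:
                    rec = _with_group(rec, 0)
                    subset.append(rec)
            path = out_path(g)
            write_any(path, sub_header, subset, compression)
            results.append((path, len(subset)))
        return results

    if header.num_read_groups != 1:
        raise Slow5Error(
            f"{spec.mode} split requires a single read group; "
            f"input has {header.num_read_groups} (split by group first)"
        )
    sizes = _chunk_sizes(len(records), spec)
    pos = 0
    for ordinal, size in enumerate(sizes):
        chunk = records[pos : pos + size]
        pos += size
        path = out_path(ordinal)
        write_any(path, header, chunk, compression)
        results.append((path, size))
    return results


def _with_group(rec: SignalRecord, group: int) -> SignalRecord:
    return SignalRecord(
        read_id=rec.read_id,
        read_group=group,
        digitisation=rec.digitisation,
        offset=rec.offset,
        range=rec.range,
        sampling_rate=rec.sampling_rate,
        raw_signal=rec.raw_signal,
        len_raw_signal=rec.len_raw_signal,
        aux=dict(rec.aux),
    )


# ---------------------------------------------------------------------------
# get


def get_many(
    input_path,
    read_ids: Sequence[str],
    output=None,
    skip_absent: bool = False,
    spec: CompressionSpec | None = None,
) -> tuple[list[SignalRecord], int]:
    """Fetch records by read_id, in request order.

    Builds (or rebuilds a stale) index on demand. Returns (records, number
    skipped); with ``skip_absent`` absent ids are omitted and counted,
    otherwise the first absent id raises, naming itself. If *output* is
    given the records are also written there.
    """
    input_path = Path(input_path)
    idx_path = default_index_path(input_path)
    index = None
    if idx_path.exists():
        try:
            index = load_index(idx_path, input_path)
        except Slow5Error:
            index = None
    if index is None:
        build_index(input_path, idx_path)
        index = load_index(idx_path, input_path)
    records: list[SignalRecord] = []
    skipped = 0
    with RandomAccessor(input_path, index) as acc:
        header = acc.header
        for rid in read_ids:
            try:
                records.append(acc.get(rid))
            except ReadIdNotFoundError:
                if skip_absent:
                    skipped += 1
                else:
                    raise
    if output is not None:
        out_spec = spec or header.compression or DEFAULT_SPEC
        write_any(output, header, records, out_spec)
    return records, skipped


# ---------------------------------------------------------------------------
# view / convert


def view_convert(
    input_path,
    output,
    target_form: str | None = None,
    spec: CompressionSpec = DEFAULT_SPEC,
) -> int:
    """Convert between SLOW5 and BLOW5 (and between compression specs).

    ``target_form`` is "slow5" or "blow5"; if None it is inferred from the
    output extension (a non-path output such as stdout implies slow5 text).
    Records and header survive field-for-field.
    """
    header, records = read_any(input_path)
    if target_form is None:
        if isinstance(output, (str, Path)):
            target_form = "blow5" if Path(output).suffix == BLOW5_SUFFIX else "slow5"
        else:
            target_form = "slow5"
    if target_form == "slow5":
        return write_slow5(header, records, output)
    if target_form == "blow5":
        return write_blow5(header, records, output, spec)
    raise Slow5Error(f"unknown target form {target_form!r}")


# ---------------------------------------------------------------------------
# stats


@dataclass(frozen=True)
class StatsReport:
    record_count: int
    num_read_groups: int
    compression: CompressionSpec | None
    primary_fields: tuple[str, ...]
    aux_fields: tuple[tuple[str, str], ...]
    per_group_counts: tuple[int, ...]


def stats(input_path) -> StatsReport:
    """Summarize a file in a single linear pass.

    For BLOW5 the pass reads frames through a 128 KiB buffer and
    decompresses only up to each record's read_group (partial decompression
    under zlib/none) rather than parsing full records.
    """
    input_path = Path(input_path)
    ok, defect = quickcheck(input_path)
    if not ok:
        raise Slow5Error(f"malformed file: {defect}")
    if is_blow5_path(input_path):
        with Blow5Reader(input_path) as reader:
            counts = [0] * reader.header.num_read_groups
            total = 0
            for _, frame in reader.frames():
                peek = codec.peek_record_prefix(
                    frame[4:], reader.spec.record_method, include_group=True
                )
                counts[peek.read_group] += 1
                total += 1
            return StatsReport(
                record_count=total,
                num_read_groups=reader.header.num_read_groups,
                compression=reader.spec,
                primary_fields=PRIMARY_COLUMNS,
                aux_fields=reader.header.aux_schema,
                per_group_counts=tuple(counts),
            )
    header, records = read_slow5(input_path)
    counts = [0] * header.num_read_groups
    total = 0
    for rec in records:
        counts[rec.read_group] += 1
        total += 1
    return StatsReport(
        record_count=total,
        num_read_groups=header.num_read_groups,
        compression=None,
        primary_fields=PRIMARY_COLUMNS,
        aux_fields=header.aux_schema,
        per_group_counts=tuple(counts),
    )


# ---------------------------------------------------------------------------
# quickcheck


def quickcheck(input_path) -> tuple[bool, str | None]:
    """Fast structural integrity test; returns (ok, first defect or None).

    For BLOW5: magic, header parse, first frame parse, EOF marker. Does not
    read every record. For SLOW5 text: header parse plus first record row.
    """
    input_path = Path(input_path)
    try:
        with open(input_path, "rb") as fh:
            magic = fh.read(8)
    except OSError as exc:
        return False, str(exc)
    if magic == MAGIC:
        try:
            with Blow5Reader(input_path) as reader:
                reader._check_eof_marker()
                batch = reader.next_batch(1)
                if batch:
                    decode_frame(batch[0][1], reader.header, reader.spec)
        except Slow5Error as exc:
            kind = "missing EOF marker" if "EOF" in str(exc) else "record parse failure"
            return False, f"{kind}: {exc}"
        return True, None
    if Path(input_path).suffix == SLOW5_SUFFIX:
        try:
            header, records = read_slow5(input_path)
            next(records, None)
        except Slow5Error as exc:
            return False, f"parse failure: {exc}"
        return True, None
    return False, f"not a SLOW5/BLOW5 file (magic {magic!r})"


# ---------------------------------------------------------------------------
# skim


def skim(input_path, selection="read_ids", sink=None) -> list[str]:
    """Print selected components of a file without full processing.

    *selection* is "header", "read_ids", or a list of column names.
    read_ids of a BLOW5 come from partial decompression under zlib/none.
    Returns the emitted lines; if *sink* is given they are also written.
    """
    input_path = Path(input_path)
    lines: list[str] = []
    if selection == "header":
        if is_blow5_path(input_path):
            with Blow5Reader(input_path) as reader:
                text = reader.header_block.decode("utf-8")
        else:
            header, _ = read_slow5(input_path)
            text = header_text(header)
        lines = text.rstrip("\n").split("\n")
    elif selection == "read_ids":
        if is_blow5_path(input_path):
            with Blow5Reader(input_path) as reader:
                for _, frame in reader.frames():
                    lines.append(
                        codec.peek_read_id(frame[4:], reader.spec.record_method)
                    )
        else:
            _, records = read_slow5(input_path)
            lines = [rec.read_id for rec in records]
    else:
        header, records = read_any(input_path)
        valid = list(PRIMARY_COLUMNS) + [name for name, _ in header.aux_schema]
        for col in selection:
            if col not in valid:
                raise Slow5Error(
                    f"unknown column {col!r}; valid columns: {', '.join(valid)}"
                )
        from .ascii_format import record_row

        for rec in records:
            full = record_row(rec, header).split("\t")
            by_name = dict(zip(valid, full))
            lines.append("\t".join(by_name[c] for c in selection))
    if sink is not None:
        for line in lines:
            sink.write(line + "\n")
    return lines
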