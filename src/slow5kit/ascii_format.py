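"""The human-readable tab-separated SLOW5 text form.

Layout, in order:

    #slow5_version<TAB>0.1.0
    #num_read_groups<TAB>N
    @attribute<TAB>value_g0<TAB>value_g1 ...      (one line per attribute)
    #string<TAB>uint32<TAB>...                    (types line)
    #read_id<TAB>read_group<TAB>...               (column names line)
    <one tab-separated row per record>

Arrays are comma-separated; a missing auxiliary value is the "." token.
Attribute lines are emitted in lexicographic key order and floats use
shortest round-trip decimals, so writing the same data twice is
byte-identical. Line endings are "\\n"; "\\r\\n" is tolerated on read.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator
from pathlib import Path

import numpy as np

from .errors import ParseError, Slow5Error
from .model import (
    AUX_TYPE_TAGS,
    PRIMARY_COLUMNS,
    PRIMARY_TYPES,
    FileHeader,
    SignalRecord,
    validate_record,
)

MISSING_TOKEN = "."


def _fmt_float(x: float) -> str:
    # repr() gives the shortest decimal that round-trips exactly
    return repr(float(x))


def _fmt_aux(tag: str, value) -> str:
    if value is None:
        return MISSING_TOKEN
    if tag == "int16_array":
        return ",".join(str(int(v)) for v in np.asarray(value, np.int16))
    if tag in ("float", "double"):
        return _fmt_float(value)
    if tag in ("char", "string"):
        return str(value)
    return str(int(value))


def _parse_aux(tag: str, token: str, line_no: int):
    if token == MISSING_TOKEN and tag not in ("char", "string"):
        return None
    try:
        if tag == "int16_array":
            if token == "":
                return np.empty(0, np.int16)
            return np.array([int(t) for t in token.split(",")], np.int16)
        if tag in ("float", "double"):
            return float(token)
        if tag == "char":
            return None if token == MISSING_TOKEN else token
        if tag == "string":
            return None if token == MISSING_TOKEN else token
        return int(token)
    except ValueError as exc:
        raise ParseError(f"bad {tag} value {token!r}", line_no) from exc


def header_text(header: FileHeader) -> str:
    """The SLOW5 header lines for *header* (also the BLOW5 header block)."""
    lines = [
        f"#slow5_version\t{header.version}",
        f"#num_read_groups\t{header.num_read_groups}",
    ]
    keys = sorted({k for g in header.group_attributes for k in g})
    for key in keys:
        values = "\t".join(g.get(key, "") for g in header.group_attributes)
        lines.append(f"@{key}\t{values}")
    types = list(PRIMARY_TYPES) + [tag for _, tag in header.aux_schema]
    names = list(PRIMARY_COLUMNS) + [name for name, _ in header.aux_schema]
    lines.append("#" + "\t".join(types))
    lines.append("#" + "\t".join(names))
    return "\n".join(lines) + "\n"


def record_row(record: SignalRecord, header: FileHeader) -> str:
    """One tab-separated data row (no trailing newline)."""
    fields = [
        record.read_id,
        str(record.read_group),
        _fmt_float(record.digitisation),
        _fmt_float(record.offset),
        _fmt_float(record.range),
        _fmt_float(record.sampling_rate),
        str(record.len_raw_signal),
        ",".join(str(int(v)) for v in record.raw_signal),
    ]
    for name, tag in header.aux_schema:
        fields.append(_fmt_aux(tag, record.aux.get(name)))
    return "\t".join(fields)


def write_slow5(
    header: FileHeader,
    records: Iterable[SignalRecord],
    sink,
) -> int:
    """Write header + records as SLOW5 text; returns the record count.

    *sink* is a text file object or a path. Records failing validation abort
    the write (partial output may remain on a path sink).
    """
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            return write_slow5(header, records, fh)
    sink.write(header_text(header))
    count = 0
    for record in records:
        report = validate_record(record, header)
        if not report.ok:
            raise Slow5Error(
                f"record {record.read_id!r} failed validation: "
                + "; ".join(report.violations)
            )
        sink.write(record_row(record, header))
        sink.write("\n")
        count += 1
    return count


# ---------------------------------------------------------------------------
# reading


def _header_from_lines(line_iter, start_line: int = 1):
    """Parse header lines; returns (header, next_line_number).

    *line_iter* must yield already-stripped lines. Stops after consuming the
    column-names line.
    """
    no = start_line

    def next_line():
        nonlocal no
        try:
            line = next(line_iter)
        except StopIteration:
            raise ParseError("unexpected end of header", no) from None
        no += 1
        return line

    try:
        first = next(line_iter)
    except StopIteration:
        raise ParseError("missing version line (empty source)", no) from None
    no += 1
    parts = first.split("\t")
    if parts[0] != "#slow5_version" or len(parts) != 2:
        raise ParseError("missing version line", start_line)
    version = parts[1]
    parts = next_line().split("\t")
    if parts[0] != "#num_read_groups" or len(parts) != 2:
        raise ParseError("missing num_read_groups line", no - 1)
    try:
        num_groups = int(parts[1])
    except ValueError:
        raise ParseError(f"bad read-group count {parts[1]!r}", no - 1) from None
    if num_groups < 1:
        raise ParseError("num_read_groups must be >= 1", no - 1)

    group_attributes: list[dict[str, str]] = [dict() for _ in range(num_groups)]
    line = next_line()
    while line.startswith("@"):
        parts = line.split("\t")
        key = parts[0][1:]
        values = parts[1:]
        if len(values) != num_groups:
            raise ParseError(
                f"attribute {key!r} has {len(values)} values for "
                f"{num_groups} read groups",
                no - 1,
            )
        for g, v in zip(group_attributes, values):
            g[key] = v
        line = next_line()

    if not line.startswith("#"):
        raise ParseError("expected types line", no - 1)
    types = line[1:].split("\t")
    names_line = next_line()
    if not names_line.startswith("#"):
        raise ParseError("expected column-names line", no - 1)
    names = names_line[1:].split("\t")
    if len(types) != len(names):
        raise ParseError("types line and column line lengths differ", no - 1)
    if tuple(names[: len(PRIMARY_COLUMNS)]) != PRIMARY_COLUMNS:
        raise ParseError(
            f"primary columns must be {list(PRIMARY_COLUMNS)}", no - 1
        )
    if tuple(types[: len(PRIMARY_TYPES)]) != PRIMARY_TYPES:
        raise ParseError(
            f"primary column types must be {list(PRIMARY_TYPES)}", no - 1
        )
    aux_schema = []
    for name, tag in zip(
        names[len(PRIMARY_COLUMNS) :], types[len(PRIMARY_TYPES) :]
    ):
        if tag not in AUX_TYPE_TAGS:
            raise ParseError(f"unknown aux type tag {tag!r}", no - 1)
        aux_schema.append((name, tag))
    header = FileHeader(
        version=version,
        num_read_groups=num_groups,
        group_attributes=group_attributes,
        aux_schema=tuple(aux_schema),
    )
    return header, no


def parse_header_text(text: str) -> FileHeader:
    """Parse a standalone header block (as stored in a BLOW5 file)."""
    lines = iter(text.splitlines())
    header, _ = _header_from_lines(lines)
    return header


def parse_record_row(line: str, header: FileHeader, line_no: int = 0) -> SignalRecord:
    fields = line.split("\t")
    expected = len(PRIMARY_COLUMNS) + len(header.aux_schema)
    if len(fields) != expected:
        raise ParseError(
            f"row has {len(fields)} columns, schema demands {expected}", line_no
        )
    try:
        read_group = int(fields[1])
        digitisation = float(fields[2])
        offset = float(fields[3])
        range_ = float(fields[4])
        sampling_rate = float(fields[5])
        n = int(fields[6])
        if fields[7] == "":
            raw = np.empty(0, np.int16)
        else:
            raw = np.array([int(t) for t in fields[7].split(",")], np.int16)
    except ValueError as exc:
        raise ParseError(f"bad primary field: {exc}", line_no) from exc
    aux = {}
    for (name, tag), token in zip(header.aux_schema, fields[len(PRIMARY_COLUMNS) :]):
        aux[name] = _parse_aux(tag, token, line_no)
    return SignalRecord(
        read_id=fields[0],
        read_group=read_group,
        digitisation=digitisation,
        offset=offset,
        range=range_,
        sampling_rate=sampling_rate,
        raw_signal=raw,
        len_raw_signal=n,
        aux=aux,
    )


def read_slow5(source) -> tuple[FileHeader, Iterator[SignalRecord]]:
    """Parse SLOW5 text; returns (header, lazy record iterator).

    *source* is a text file object or a path. Parse errors name the
    offending 1-based line number.
    """
    if isinstance(source, (str, Path)):
        fh = open(source, "r", encoding="utf-8", newline="")
        own = True
    else:
        fh = source
        own = False

    stripped = (line.rstrip("\r\n") for line in fh)
    header, next_no = _header_from_lines(stripped)

    def rows() -> Iterator[SignalRecord]:
        no = next_no
        try:
            for line in stripped:
                if line == "":
                    no += 1
                    continue
                yield parse_record_row(line, header, no)
                no += 1
        finally:
            if own:
                fh.close()
    return header, rows()


def read_slow5_all(source) -> tuple[FileHeader, list[SignalRecord]]:
    header, records = read_slow5(source)
    return header, list(records)
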