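"""Domain model: signal records, file headers, compression specs.

A nanopore read is a time series of signed 16-bit ADC samples plus the
calibration scalars needed to convert counts to picoamperes:

    pA_i = (raw_i + offset) * range / digitisation

Records belong to a *read group* — a set of reads sharing acquisition
metadata (one run / flow cell). The file header carries one attribute map
per group plus the ordered auxiliary-field schema that every record's
``aux`` mapping must follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import CalibrationError

FORMAT_VERSION = "0.1.0"


class RecordCompression(str, Enum):
    """Record-layer (whole payload) block compression."""

    NONE = "none"
    ZLIB = "zlib"
    ZSTD = "zstd"


class SignalCompression(str, Enum):
    """Signal-layer encoding applied to the raw samples before packing."""

    NONE = "none"
    SVB_ZD = "svb-zd"


@dataclass(frozen=True)
class CompressionSpec:
    """(record method, signal method) pair governing BLOW5 encoding.

    The two layers are independent; all six combinations are legal. The
    default is zlib on the record and svb-zd on the signal.
    """

    record_method: RecordCompression = RecordCompression.ZLIB
    signal_method: SignalCompression = SignalCompression.SVB_ZD


DEFAULT_SPEC = CompressionSpec()

#: Closed set of auxiliary-field type tags. Unknown tags are a parse error:
#: a lossless round trip requires a closed type system.
AUX_TYPE_TAGS = (
    "int8",
    "int16",
    "int32",
    "int64",
    "uint8",
    "uint16",
    "uint32",
    "uint64",
    "float",
    "double",
    "char",
    "string",
    "int16_array",
)

#: Primary column names, in file order.
PRIMARY_COLUMNS = (
    "read_id",
    "read_group",
    "digitisation",
    "offset",
    "range",
    "sampling_rate",
    "len_raw_signal",
    "raw_signal",
)

#: Type tags of the primary columns (for the ASCII types line).
PRIMARY_TYPES = (
    "string",
    "uint32",
    "double",
    "double",
    "double",
    "double",
    "uint64",
    "int16_array",
)

INT16_MIN, INT16_MAX = -(2**15), 2**15 - 1


@dataclass(eq=False)
class SignalRecord:
    """One nanopore read: identifiers, calibration, raw signal, aux values.

    ``aux`` maps auxiliary field name -> value (int, float, str or int16
    ndarray) or ``None`` for an explicitly missing value. Keys must match
    the owning header's schema, in schema order.
    """

    read_id: str
    read_group: int = 0
    digitisation: float = 8192.0
    offset: float = 0.0
    range: float = 1402.882
    sampling_rate: float = 4000.0
    raw_signal: np.ndarray = field(default_factory=lambda: np.empty(0, np.int16))
    len_raw_signal: int | None = None
    aux: dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        self.raw_signal = np.asarray(self.raw_signal, dtype=np.int16)
        if self.len_raw_signal is None:
            self.len_raw_signal = int(self.raw_signal.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignalRecord):
            return NotImplemented
        if (
            self.read_id != other.read_id
            or self.read_group != other.read_group
            or self.digitisation != other.digitisation
            or self.offset != other.offset
            or self.range != other.range
            or self.sampling_rate != other.sampling_rate
            or self.len_raw_signal != other.len_raw_signal
            or not np.array_equal(self.raw_signal, other.raw_signal)
        ):
            return False
        if list(self.aux) != list(other.aux):
            return False
        for k, v in self.aux.items():
            w = other.aux[k]
            if isinstance(v, np.ndarray) or isinstance(w, np.ndarray):
                if not (isinstance(v, np.ndarray) and isinstance(w, np.ndarray)):
                    return False
                if not np.array_equal(v, w):
                    return False
            elif v != w or type(v) is not type(w):
                return False
        return True


@dataclass(eq=True)
class FileHeader:
    """Per-file metadata: read-group attribute maps and the aux schema.

    ``group_attributes`` has one attribute-name -> string-value map per
    read group; all maps share an identical key set. ``aux_schema`` is an
    ordered tuple of (field name, type tag).
    """

    version: str = FORMAT_VERSION
    num_read_groups: int = 1
    group_attributes: list[dict[str, str]] = field(default_factory=lambda: [{}])
    aux_schema: tuple[tuple[str, str], ...] = ()
    compression: CompressionSpec | None = None

    def __eq__(self, other) -> bool:
        # Attribute order within a map is irrelevant; compression is a
        # container property, not part of header identity.
        if not isinstance(other, FileHeader):
            return NotImplemented
        return (
            self.version == other.version
            and self.num_read_groups == other.num_read_groups
            and self.group_attributes == other.group_attributes
            and self.aux_schema == other.aux_schema
        )


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple[str, ...] = ()


def validate_record(record: SignalRecord, header: FileHeader) -> ValidationReport:
    """Check a record against its invariants and the owning header.

    Violations are reported, never raised; the report is a pure function of
    its inputs.
    """
    violations: list[str] = []
    if not record.read_id:
        violations.append("empty read_id")
    if "\t" in record.read_id or "\n" in record.read_id or "\r" in record.read_id:
        violations.append("read_id contains tab or newline")
    if record.read_group < 0:
        violations.append("negative read_group")
    elif record.read_group >= header.num_read_groups:
        violations.append(
            f"read_group out of range ({record.read_group} >= {header.num_read_groups})"
        )
    if record.len_raw_signal != record.raw_signal.size:
        violations.append(
            f"signal length mismatch (len_raw_signal={record.len_raw_signal}, "
            f"actual={record.raw_signal.size})"
        )
    if record.raw_signal.size and (
        record.raw_signal.min() < INT16_MIN or record.raw_signal.max() > INT16_MAX
    ):
        violations.append("raw_signal sample outside int16 range")
    schema_keys = [name for name, _ in header.aux_schema]
    if list(record.aux) != schema_keys:
        violations.append(
            f"aux keys {list(record.aux)} do not match schema {schema_keys}"
        )
    if record.digitisation <= 0:
        violations.append("non-positive digitisation")
    if record.range <= 0:
        violations.append("non-positive range")
    if record.sampling_rate <= 0:
        violations.append("non-positive sampling_rate")
    return ValidationReport(ok=not violations, violations=tuple(violations))


def signal_to_pA(record: SignalRecord) -> np.ndarray:
    """Convert raw ADC samples to picoamperes.

    pA_i = (raw_i + offset) * range / digitisation. The output has the same
    length as the raw signal.
    """
    if record.digitisation <= 0:
        raise CalibrationError(
            f"digitisation must be positive, got {record.digitisation}"
        )
    raw = record.raw_signal.astype(np.float64)
    return (raw + record.offset) * record.range / record.digitisation
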