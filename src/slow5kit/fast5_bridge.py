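"""Lossless FAST5 <-> SLOW5/BLOW5 conversion.

Multi-read FAST5 layout handled here (one HDF5 group per read):

    /read_<read_id>/Raw/Signal            int16 dataset
    /read_<read_id>/Raw                   attrs: read_number, start_time,
                                          start_mux, median_before
    /read_<read_id>/channel_id            attrs: digitisation, offset, range,
                                          sampling_rate, channel_number
    /read_<read_id>/tracking_id           run metadata attrs
    /read_<read_id>/context_tags          acquisition attrs

``f2s`` maps calibration attributes to primary fields, tracking_id and
context_tags to header read-group attributes (one read group per FAST5
file), and the remaining per-read attributes to auxiliary fields. ``s2f``
restores them, re-batching at 4000 reads per file (the MinKNOW default).
Conversion is lossless: every captured value survives the round trip, with
floating-point attributes bit-preserved.
"""

from __future__ import annotations

import logging
import time
from collections import deque
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .errors import MalformedFast5Error, Slow5Error
from .model import (
    CompressionSpec,
    DEFAULT_SPEC,
    FileHeader,
    SignalRecord,
)
from .toolkit import quickcheck, read_any, write_any

logger = logging.getLogger(__name__)

FAST5_VERSION = "2.2"
READS_PER_FAST5 = 4000

#: Auxiliary schema for converted files, with each field's FAST5 home.
AUX_SCHEMA = (
    ("channel_number", "string"),
    ("median_before", "double"),
    ("read_number", "int32"),
    ("start_mux", "uint8"),
    ("start_time", "uint64"),
)
_RAW_AUX = ("median_before", "read_number", "start_mux", "start_time")
_CALIBRATION = ("digitisation", "offset", "range", "sampling_rate")

#: Header attributes restored into tracking_id vs context_tags on s2f.
TRACKING_KEYS = (
    "run_id",
    "flow_cell_id",
    "device_id",
    "device_type",
    "exp_start_time",
    "sample_id",
)
CONTEXT_KEYS = (
    "experiment_type",
    "sample_frequency",
    "sequencing_kit",
)

#: Reserved group for aux fields with no defined FAST5 location.
EXTRA_GROUP = "slow5_extra"


def _attr_str(value) -> str:
    if isinstance(value, bytes):
        return value.decode("utf-8")
    return str(value)


def _read_one(group: h5py.Group, name: str) -> SignalRecord:
    read_id = name[len("read_") :]
    if "Raw" not in group or "Signal" not in group["Raw"]:
        raise MalformedFast5Error(f"read {read_id!r} has no Raw/Signal dataset")
    if "channel_id" not in group:
        raise MalformedFast5Error(f"read {read_id!r} has no channel_id group")
    channel = group["channel_id"]
    cal = {}
    for key in _CALIBRATION:
        if key not in channel.attrs:
            raise MalformedFast5Error(
                f"read {read_id!r} missing calibration attribute {key!r}"
            )
        cal[key] = float(channel.attrs[key])
    raw = np.asarray(group["Raw"]["Signal"][()], dtype=np.int16)
    raw_attrs = group["Raw"].attrs
    aux: dict[str, object] = {
        "channel_number": (
            _attr_str(channel.attrs["channel_number"])
            if "channel_number" in channel.attrs
            else None
        )
    }
    for key in _RAW_AUX:
        if key in raw_attrs:
            v = raw_attrs[key]
            aux[key] = float(v) if key == "median_before" else int(v)
        else:
            aux[key] = None
    aux = {name: aux[name] for name, _ in AUX_SCHEMA}
    return SignalRecord(
        read_id=read_id,
        read_group=0,
        digitisation=cal["digitisation"],
        offset=cal["offset"],
        range=cal["range"],
        sampling_rate=cal["sampling_rate"],
        raw_signal=raw,
        aux=aux,
    )


def _run_attributes(group: h5py.Group) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for sub in ("tracking_id", "context_tags"):
        if sub in group:
            for k, v in group[sub].attrs.items():
                attrs[k] = _attr_str(v)
    return attrs


def fast5_to_slow5(
    fast5_path,
    output_path,
    spec: CompressionSpec = DEFAULT_SPEC,
) -> int:
    """Convert one multi-read FAST5 file to SLOW5/BLOW5; returns read count.

    The file becomes one read group whose attributes are the union of
    tracking_id and context_tags.
    """
    fast5_path = Path(fast5_path)
    records: list[SignalRecord] = []
    group_attrs: dict[str, str] = {}
    with h5py.File(fast5_path, "r") as f:
        names = [n for n in f.keys() if n.startswith("read_")]
        for i, name in enumerate(names):
            group = f[name]
            if i == 0:
                group_attrs = _run_attributes(group)
            records.append(_read_one(group, name))
    header = FileHeader(
        num_read_groups=1,
        group_attributes=[group_attrs],
        aux_schema=AUX_SCHEMA,
    )
    return write_any(output_path, header, records, spec)


def slow5_to_fast5(input_path, output_dir, reads_per_file: int = READS_PER_FAST5):
    """Convert SLOW5/BLOW5 back to multi-read FAST5; returns output paths.

    Emits one or more files per read group (no file mixes groups), up to
    *reads_per_file* reads each. Aux fields without a defined FAST5
    location go under the reserved ``slow5_extra`` group with a warning.
    """
    input_path = Path(input_path)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    header, stream = read_any(input_path)
    by_group: list[list[SignalRecord]] = [
        [] for _ in range(header.num_read_groups)
    ]
    for rec in stream:
        by_group[rec.read_group].append(rec)

    known_aux = {name for name, _ in AUX_SCHEMA}
    extra_aux = [name for name, _ in header.aux_schema if name not in known_aux]
    if extra_aux:
        logger.warning(
            "aux fields %s have no defined FAST5 location; storing under %r",
            extra_aux,
            EXTRA_GROUP,
        )

    paths: list[Path] = []
    stem = input_path.stem
    for g, records in enumerate(by_group):
        attrs = header.group_attributes[g]
        tracking = {k: v for k, v in attrs.items() if k in TRACKING_KEYS}
        context = {k: v for k, v in attrs.items() if k in CONTEXT_KEYS}
        other = {
            k: v
            for k, v in attrs.items()
            if k not in TRACKING_KEYS and k not in CONTEXT_KEYS
        }
        tracking.update(other)  # unclassified run attributes stay readable
        for ordinal in range(0, max(1, -(-len(records) // reads_per_file))):
            chunk = records[
                ordinal * reads_per_file : (ordinal + 1) * reads_per_file
            ]
            if not chunk and ordinal > 0:
                break
            path = output_dir / f"{stem}_g{g}_{ordinal:04d}.fast5"
            _write_fast5(path, chunk, tracking, context, extra_aux)
            paths.append(path)
    return paths


def _write_fast5(path, records, tracking, context, extra_aux):
    # track_order keeps read groups in insertion order, as MinKNOW writes them
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["file_version"] = FAST5_VERSION
        f.attrs["file_type"] = "multi-read"
        for rec in records:
            g = f.create_group(f"read_{rec.read_id}")
            g.attrs["run_id"] = tracking.get("run_id", "")
            raw = g.create_group("Raw")
            raw.create_dataset(
                "Signal", data=rec.raw_signal.astype(np.int16), dtype="<i2"
            )
            for key in _RAW_AUX:
                value = rec.aux.get(key)
                if value is None:
                    continue
                if key == "median_before":
                    raw.attrs.create(key, np.float64(value))
                elif key == "read_number":
                    raw.attrs.create(key, np.int32(value))
                elif key == "start_mux":
                    raw.attrs.create(key, np.uint8(value))
                else:
                    raw.attrs.create(key, np.uint64(value))
            channel = g.create_group("channel_id")
            channel.attrs.create("digitisation", np.float64(rec.digitisation))
            channel.attrs.create("offset", np.float64(rec.offset))
            channel.attrs.create("range", np.float64(rec.range))
            channel.attrs.create("sampling_rate", np.float64(rec.sampling_rate))
            if rec.aux.get("channel_number") is not None:
                channel.attrs["channel_number"] = rec.aux["channel_number"]
            tid = g.create_group("tracking_id")
            for k, v in tracking.items():
                tid.attrs[k] = v
            ctx = g.create_group("context_tags")
            for k, v in context.items():
                ctx.attrs[k] = v
            if extra_aux:
                extra = g.create_group(EXTRA_GROUP)
                for name in extra_aux:
                    value = rec.aux.get(name)
                    if value is not None:
                        extra.attrs[name] = value


# ---------------------------------------------------------------------------
# directory conversion


@dataclass(frozen=True)
class ConversionResult:
    input_path: Path
    output_path: Path | None
    record_count: int
    error: str | None = None


def partition_evenly(items: list, workers: int) -> list[list]:
    """Split *items* into *workers* contiguous chunks, sizes differing by
    at most one, larger chunks first."""
    n = len(items)
    workers = max(1, min(workers, n)) if n else 1
    base, extra = divmod(n, workers)
    sizes = [base + 1] * extra + [base] * (workers - extra)
    out, pos = [], 0
    for s in sizes:
        out.append(items[pos : pos + s])
        pos += s
    return out


def _convert_one(src: Path, dst: Path, direction: str, spec) -> ConversionResult:
    try:
        dst.parent.mkdir(parents=True, exist_ok=True)
        if direction == "f2s":
            count = fast5_to_slow5(src, dst, spec)
            return ConversionResult(src, dst, count)
        outputs = slow5_to_fast5(src, dst)
        count = sum(
            len([k for k in h5py.File(p, "r").keys() if k.startswith("read_")])
            for p in outputs
        )
        return ConversionResult(src, dst, count)
    except Exception as exc:  # a failing file must not sink the others
        return ConversionResult(src, None, 0, error=str(exc))


def convert_directory(
    input_dir,
    output_dir,
    direction: str = "f2s",
    workers: int = 1,
    spec: CompressionSpec = DEFAULT_SPEC,
) -> list[ConversionResult]:
    """Recursively convert a directory tree; returns a manifest sorted by
    input path.

    Files are found by extension (.fast5 for f2s; .blow5/.slow5 for s2f)
    and distributed as evenly as possible across workers; one output per
    input, mirroring relative paths. Results are independent of the worker
    count. Any failure is recorded in the manifest, not raised.
    """
    input_dir = Path(input_dir)
    output_dir = Path(output_dir)
    if direction not in ("f2s", "s2f"):
        raise Slow5Error(f"unknown direction {direction!r}")
    exts = (".fast5",) if direction == "f2s" else (".blow5", ".slow5")
    files = sorted(
        p for p in input_dir.rglob("*") if p.is_file() and p.suffix in exts
    )

    def target(src: Path) -> Path:
        rel = src.relative_to(input_dir)
        if direction == "f2s":
            return output_dir / rel.with_suffix(".blow5")
        return output_dir / rel.parent / rel.stem  # s2f emits a directory

    jobs = [(src, target(src)) for src in files]
    results: list[ConversionResult] = []
    if workers <= 1 or len(jobs) <= 1:
        for src, dst in jobs:
            results.append(_convert_one(src, dst, direction, spec))
    else:
        chunks = partition_evenly(jobs, workers)
        with ThreadPoolExecutor(max_workers=len(chunks)) as pool:
            futures = [
                pool.submit(
                    lambda chunk: [
                        _convert_one(s, d, direction, spec) for s, d in chunk
                    ],
                    chunk,
                )
                for chunk in chunks
            ]
            for fut in futures:
                results.extend(fut.result())
    return sorted(results, key=lambda r: str(r.input_path))


# ---------------------------------------------------------------------------
# real-time conversion


@dataclass
class WatchEvent:
    input_path: Path
    output_path: Path | None
    record_count: int
    status: str  # converted | failed | deleted-source
    detail: str | None = None


def watch_and_convert(
    run_dir,
    output_dir,
    max_workers: int = 1,
    stop_after: int | None = None,
    timeout: float = 60.0,
    poll_interval: float = 5.0,
    delete_sources: bool = False,
    spec: CompressionSpec = DEFAULT_SPEC,
) -> list[WatchEvent]:
    """Watch *run_dir* for newly appearing FAST5 files and convert them.

    Polls at ``poll_interval`` seconds; a file counts as complete once its
    size is unchanged across two polls. At most ``max_workers`` conversions
    run at a time; excess files queue FIFO in detection order. With
    ``delete_sources`` the FAST5 is removed only after the output passes
    quickcheck and its record count matches the input's read count. Stops
    after ``stop_after`` conversions or ``timeout`` seconds.
    """
    run_dir = Path(run_dir)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    seen: dict[Path, int] = {}  # last observed size; -1 = queued/done
    pending: deque[Path] = deque()
    events: list[WatchEvent] = []
    deadline = time.monotonic() + timeout

    def convert(src: Path) -> WatchEvent:
        dst = output_dir / src.with_suffix(".blow5").name
        try:
            with h5py.File(src, "r") as f:
                n_reads = sum(1 for k in f.keys() if k.startswith("read_"))
            count = fast5_to_slow5(src, dst, spec)
            ok, defect = quickcheck(dst)
            if not ok or count != n_reads:
                return WatchEvent(
                    src, dst, count, "failed",
                    defect or f"record count {count} != read count {n_reads}",
                )
        except Exception as exc:
            return WatchEvent(src, None, 0, "failed", str(exc))
        if delete_sources:
            src.unlink()
            return WatchEvent(src, dst, count, "deleted-source")
        return WatchEvent(src, dst, count, "converted")

    with ThreadPoolExecutor(max_workers=max_workers) as pool:
        futures = []
        while True:
            for path in sorted(run_dir.glob("*.fast5")):
                size = path.stat().st_size if path.exists() else -1
                prev = seen.get(path)
                if prev == -1:
                    continue
                if prev is not None and prev == size:
                    seen[path] = -1
                    pending.append(path)  # stable across two polls
                else:
                    seen[path] = size
            while pending:
                futures.append(pool.submit(convert, pending.popleft()))
            done = [f for f in futures if f.done()]
            for f in done:
                events.append(f.result())
                futures.remove(f)
            total = len(events) + len(futures)
            if stop_after is not None and len(events) >= stop_after:
                break
            if time.monotonic() > deadline:
                logger.warning("watch timed out with %d conversions pending",
                               len(futures))
                break
            time.sleep(poll_interval)
        for f in futures:
            events.append(f.result())
    events.sort(key=lambda e: str(e.input_path))
    return events
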