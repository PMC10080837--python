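"""Seeded synthetic nanopore datasets for testing and demonstration.

The signal model is a random walk with occasional level shifts: ionic
current through a pore dwells at a roughly constant level while one k-mer
occupies the sensing region, then jumps when the strand translocates. That
structure is what makes delta-based compression worthwhile — pure white
noise would defeat svb-zd and a constant would make it trivial — so the
generator emulates it with segment-wise baselines plus small integer steps.

Everything is a deterministic function of the seed: identical configs give
field-identical records and byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import Slow5Error
from .fast5_bridge import AUX_SCHEMA, READS_PER_FAST5, _write_fast5
from .model import FileHeader, SignalRecord

#: Calibration constants typical of a MinION R9.4.1 flow cell.
DIGITISATION = 8192.0
RANGE_PA = 1402.882
SAMPLING_RATE = 4000.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    Defaults mirror a MinKNOW acquisition at desk scale: 16-bit signals of
    a few thousand samples, batches of 4000 reads per FAST5 file, one read
    group per run.
    """

    seed: int = 0
    n_reads: int = 100
    reads_per_fast5: int = READS_PER_FAST5
    min_signal_len: int = 500
    max_signal_len: int = 5000
    step_scale: float = 3.0  # within-segment random-walk step std (ADC counts)
    baseline: float = 500.0  # mean pore current level (ADC counts)
    level_shift_scale: float = 60.0  # between-segment jump std
    mean_segment_len: int = 40  # samples per dwell segment
    n_read_groups: int = 1
    missing_aux_rate: float = 0.05
    run_prefix: str = "run"


def _uuid_like(rng: np.random.Generator) -> str:
    h = rng.integers(0, 16, 32)
    s = "".join("0123456789abcdef"[int(v)] for v in h)
    return f"{s[:8]}-{s[8:12]}-{s[12:16]}-{s[16:20]}-{s[20:32]}"


def _signal(rng: np.random.Generator, n: int, cfg: SyntheticConfig) -> np.ndarray:
    if n == 0:
        return np.empty(0, np.int16)
    n_segments = max(1, int(round(n / cfg.mean_segment_len)))
    bounds = np.sort(rng.integers(0, n, n_segments - 1)) if n_segments > 1 else []
    levels = cfg.baseline + rng.normal(0, cfg.level_shift_scale, n_segments)
    base = np.empty(n)
    start = 0
    for i, end in enumerate(list(bounds) + [n]):
        base[start:end] = levels[i]
        start = end
    walk = np.cumsum(rng.normal(0, cfg.step_scale, n))
    walk -= np.linspace(0, walk[-1], n)  # keep the walk from drifting off-range
    sig = np.rint(base + walk)
    return np.clip(sig, -32768, 32767).astype(np.int16)


def group_attributes(cfg: SyntheticConfig) -> list[dict[str, str]]:
    """Deterministic per-run metadata emulating MinKNOW's tracking/context tags."""
    groups = []
    for g in range(cfg.n_read_groups):
        groups.append(
            {
                "run_id": f"{cfg.run_prefix}{cfg.seed:08d}g{g}",
                "flow_cell_id": f"FAN{10000 + cfg.seed % 10000 + g:05d}",
                "device_id": "MN12345",
                "device_type": "minion",
                "exp_start_time": "2000-01-01T00:00:00Z",
                "sample_id": f"sample_{g}",
                "experiment_type": "genomic_dna",
                "sample_frequency": str(int(SAMPLING_RATE)),
                "sequencing_kit": "sqk-lsk109",
            }
        )
    return groups


def generate_records(cfg: SyntheticConfig) -> tuple[FileHeader, list[SignalRecord]]:
    """Generate a header and records; identical configs give identical output."""
    rng = np.random.default_rng(cfg.seed)
    header = FileHeader(
        num_read_groups=cfg.n_read_groups,
        group_attributes=group_attributes(cfg),
        aux_schema=AUX_SCHEMA,
    )
    records: list[SignalRecord] = []
    for i in range(cfg.n_reads):
        n = int(rng.integers(cfg.min_signal_len, cfg.max_signal_len + 1))
        aux = {
            "channel_number": str(int(rng.integers(1, 513))),
            "median_before": (
                None
                if rng.random() < cfg.missing_aux_rate
                else float(np.round(rng.normal(220.0, 20.0), 3))
            ),
            "read_number": i + 1,
            "start_mux": int(rng.integers(1, 5)),
            "start_time": int(i * 1000 + rng.integers(0, 1000)),
        }
        records.append(
            SignalRecord(
                read_id=_uuid_like(rng),
                read_group=i % cfg.n_read_groups,
                digitisation=DIGITISATION,
                offset=float(int(rng.integers(-10, 11))),
                range=RANGE_PA,
                sampling_rate=SAMPLING_RATE,
                raw_signal=_signal(rng, n, cfg),
                aux=aux,
            )
        )
    return header, records


def generate_fast5_dataset(cfg: SyntheticConfig, output_dir, overwrite=False):
    """Write the synthetic dataset as multi-read FAST5 files.

    Emits ceil(n_reads / reads_per_fast5) files emulating a MinKNOW run
    directory. Requires a single read group (one run per directory).
    """
    if cfg.n_read_groups != 1:
        raise Slow5Error("a FAST5 run directory holds one run (one read group)")
    output_dir = Path(output_dir)
    if output_dir.exists() and any(output_dir.iterdir()) and not overwrite:
        raise Slow5Error(f"output directory {output_dir} is not empty")
    output_dir.mkdir(parents=True, exist_ok=True)
    header, records = generate_records(cfg)
    attrs = header.group_attributes[0]
    from .fast5_bridge import CONTEXT_KEYS, TRACKING_KEYS

    tracking = {k: v for k, v in attrs.items() if k in TRACKING_KEYS}
    context = {k: v for k, v in attrs.items() if k in CONTEXT_KEYS}
    paths = []
    for ordinal in range(0, max(1, -(-len(records) // cfg.reads_per_fast5))):
        chunk = records[
            ordinal * cfg.reads_per_fast5 : (ordinal + 1) * cfg.reads_per_fast5
        ]
        if not chunk and ordinal > 0:
            break
        path = output_dir / f"{attrs['run_id']}_{ordinal:04d}.fast5"
        _write_fast5(path, chunk, tracking, context, extra_aux=[])
        paths.append(path)
    return paths
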