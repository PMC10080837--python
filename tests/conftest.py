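import itertools

import pytest

from slow5kit.model import (
    CompressionSpec,
    RecordCompression,
    SignalCompression,
)
from slow5kit.simulate import SyntheticConfig, generate_records

ALL_SPECS = [
    CompressionSpec(rm, sm)
    for rm, sm in itertools.product(RecordCompression, SignalCompression)
]


@pytest.fixture(scope="session")
def small_dataset():
    """20 short synthetic reads: quick fixture for format round trips."""
    cfg = SyntheticConfig(seed=11, n_reads=20, min_signal_len=10, max_signal_len=200)
    return generate_records(cfg)


@pytest.fixture(scope="session")
def medium_dataset():
    """200 reads with edge cases injected: empty signal, int16 extremes,
    all-missing aux, maximal-ish read_id."""
    import numpy as np

    from slow5kit.fast5_bridge import AUX_SCHEMA
    from slow5kit.model import SignalRecord

    cfg = SyntheticConfig(seed=7, n_reads=200, min_signal_len=5, max_signal_len=800)
    header, records = generate_records(cfg)
    missing = {name: None for name, _ in AUX_SCHEMA}
    records[0] = SignalRecord(
        read_id="empty-signal", raw_signal=np.empty(0, np.int16), aux=missing
    )
    records[1] = SignalRecord(
        read_id="extremes",
        raw_signal=np.array([-32768, 32767, -32768, 0, 32767], np.int16),
        aux=dict(records[1].aux),
    )
    records[2] = SignalRecord(
        read_id="x" * 900,
        raw_signal=records[2].raw_signal,
        aux=dict(records[2].aux),
    )
    return header, records
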