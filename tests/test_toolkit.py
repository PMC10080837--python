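import numpy as np
import pytest

from slow5kit.blow5_format import read_blow5_all, write_blow5
from slow5kit.errors import (
    MetadataMismatchError,
    ReadIdNotFoundError,
    SchemaConflictError,
    Slow5Error,
)
from slow5kit.model import (
    CompressionSpec,
    FileHeader,
    RecordCompression,
    SignalCompression,
)
from slow5kit.simulate import SyntheticConfig, generate_records
from slow5kit.toolkit import (
    SplitSpec,
    cat,
    get_many,
    merge,
    quickcheck,
    skim,
    split,
    stats,
    view_convert,
)


def make_run(tmp_path, seed, n=10, prefix="run", name=None):
    cfg = SyntheticConfig(seed=seed, n_reads=n, min_signal_len=10,
                          max_signal_len=150, run_prefix=prefix)
    header, records = generate_records(cfg)
    path = tmp_path / (name or f"{prefix}{seed}.blow5")
    write_blow5(header, records, path)
    return path, header, records


class TestMerge:
    def test_two_runs_get_two_groups(self, tmp_path):
        p1, h1, r1 = make_run(tmp_path, 1, prefix="runA")
        p2, h2, r2 = make_run(tmp_path, 2, prefix="runB")
        out = tmp_path / "m.blow5"
        count, plan = merge([p1, p2], out)
        header, records = read_blow5_all(out)
        assert count == 20 and header.num_read_groups == 2
        assert [r.read_group for r in records] == [0] * 10 + [1] * 10
        assert [r.read_id for r in records] == [
            r.read_id for r in r1 + r2
        ]  # within-input order preserved

    def test_identical_metadata_unifies_groups(self, tmp_path):
        _, h, r = make_run(tmp_path, 3)
        p1, p2 = tmp_path / "a.blow5", tmp_path / "b.blow5"
        write_blow5(h, r[:5], p1)
        write_blow5(h, r[5:], p2)
        out = tmp_path / "u.blow5"
        count, plan = merge([p1, p2], out)
        header, records = read_blow5_all(out)
        assert header.num_read_groups == 1
        assert all(rec.read_group == 0 for rec in records)

    def test_single_input_merge_is_record_identity(self, tmp_path):
        p, h, r = make_run(tmp_path, 4)
        out = tmp_path / "one.blow5"
        count, _ = merge([p], out)
        _, records = read_blow5_all(out)
        assert records == r

    def test_conflicting_aux_schemas_refused(self, tmp_path):
        p1, h, r = make_run(tmp_path, 5)
        h2 = FileHeader(group_attributes=[{"run_id": "other"}],
                        aux_schema=(("weird", "int32"),))
        from slow5kit.model import SignalRecord

        rec = SignalRecord(read_id="q", raw_signal=np.array([1], np.int16),
                           aux={"weird": 1})
        p2 = tmp_path / "w.blow5"
        write_blow5(h2, [rec], p2)
        with pytest.raises(SchemaConflictError):
            merge([p1, p2], tmp_path / "x.blow5")

    def test_directory_inputs_expand_lexicographically(self, tmp_path):
        d = tmp_path / "runs"
        d.mkdir()
        _, h1, r1 = make_run(d, 6, prefix="runA", name="b_second.blow5")
        _, h2, r2 = make_run(d, 7, prefix="runB", name="a_first.blow5")
        out = tmp_path / "dir.blow5"
        count, _ = merge([d], out)
        _, records = read_blow5_all(out)
        assert [r.read_id for r in records] == [r.read_id for r in r2 + r1]


class TestCat:
    def test_cat_equals_merge_records_for_identical_headers(self, tmp_path):
        _, h, r = make_run(tmp_path, 8, n=12)
        parts = []
        for i in range(3):
            p = tmp_path / f"part{i}.blow5"
            write_blow5(h, r[4 * i : 4 * (i + 1)], p)
            parts.append(p)
        out_cat, out_merge = tmp_path / "c.blow5", tmp_path / "m.blow5"
        assert cat(parts, out_cat) == 12
        merge(parts, out_merge)
        assert read_blow5_all(out_cat)[1] == read_blow5_all(out_merge)[1] == r

    def test_differing_metadata_refused_without_output(self, tmp_path):
        p1, _, _ = make_run(tmp_path, 9, prefix="runA")
        p2, _, _ = make_run(tmp_path, 10, prefix="runB")
        out = tmp_path / "no.blow5"
        with pytest.raises(MetadataMismatchError):
            cat([p1, p2], out)
        assert not out.exists()

    def test_cat_single_file_is_byte_identical(self, tmp_path):
        p, _, _ = make_run(tmp_path, 11)
        out = tmp_path / "copy.blow5"
        cat([p], out)
        assert out.read_bytes() == p.read_bytes()


class TestSplit:
    def test_reads_per_file_ceiling(self, tmp_path):
        p, h, r = make_run(tmp_path, 12, n=10)
        res = split(p, tmp_path / "rp", SplitSpec("reads_per_file", 4))
        assert [n for _, n in res] == [4, 4, 2]
        back = [rec for path, _ in res for rec in read_blow5_all(path)[1]]
        assert back == r

    def test_file_count_balanced_larger_first(self, tmp_path):
        p, h, r = make_run(tmp_path, 13, n=10)
        res = split(p, tmp_path / "fc", SplitSpec("file_count", 3))
        assert [n for _, n in res] == [4, 3, 3]

    def test_more_files_than_reads_refused(self, tmp_path):
        p, _, _ = make_run(tmp_path, 14, n=3)
        with pytest.raises(Slow5Error):
            split(p, tmp_path / "x", SplitSpec("file_count", 5))

    def test_by_group_inverts_merge(self, tmp_path):
        p1, h1, r1 = make_run(tmp_path, 15, prefix="runA")
        p2, h2, r2 = make_run(tmp_path, 16, prefix="runB")
        merged = tmp_path / "m.blow5"
        merge([p1, p2], merged)
        res = split(merged, tmp_path / "g", SplitSpec("by_group"))
        assert len(res) == 2
        ha, ra = read_blow5_all(res[0][0])
        hb, rb = read_blow5_all(res[1][0])
        assert ra == r1 and rb == r2
        assert ha == h1 and hb == h2

    def test_chunk_modes_require_single_group(self, tmp_path):
        p1, _, _ = make_run(tmp_path, 17, prefix="runA")
        p2, _, _ = make_run(tmp_path, 18, prefix="runB")
        merged = tmp_path / "m.blow5"
        merge([p1, p2], merged)
        with pytest.raises(Slow5Error, match="single read group"):
            split(merged, tmp_path / "x", SplitSpec("reads_per_file", 4))


class TestGet:
    def test_request_order_and_duplicates(self, tmp_path):
        p, _, r = make_run(tmp_path, 19, n=20)
        ids = [r[5].read_id, r[2].read_id, r[5].read_id, r[19].read_id]
        records, skipped = get_many(p, ids)
        assert [x.read_id for x in records] == ids
        assert records[0] == records[2] == r[5]
        assert skipped == 0

    def test_absent_id_errors_by_name(self, tmp_path):
        p, _, _ = make_run(tmp_path, 20)
        with pytest.raises(ReadIdNotFoundError, match="ghost-read"):
            get_many(p, ["ghost-read"])

    def test_skip_flag_counts_absent(self, tmp_path):
        p, _, r = make_run(tmp_path, 21)
        records, skipped = get_many(
            p, [r[0].read_id, "ghost", r[1].read_id], skip_absent=True
        )
        assert [x.read_id for x in records] == [r[0].read_id, r[1].read_id]
        assert skipped == 1


class TestViewConvert:
    def test_blow5_slow5_blow5_composition(self, tmp_path):
        p, h, r = make_run(tmp_path, 22)
        s = tmp_path / "v.slow5"
        b = tmp_path / "v.blow5"
        view_convert(p, s)
        view_convert(s, b)
        assert read_blow5_all(b)[1] == r

    def test_closure_under_all_spec_conversions(self, tmp_path):
        from conftest import ALL_SPECS

        p, h, r = make_run(tmp_path, 23)
        prev = p
        for i, spec in enumerate(ALL_SPECS):
            nxt = tmp_path / f"conv{i}.blow5"
            view_convert(prev, nxt, "blow5", spec)
            prev = nxt
        assert read_blow5_all(prev)[1] == r

    def test_view_to_stream_prints_slow5_text(self, tmp_path, capsys):
        import io

        p, h, r = make_run(tmp_path, 24, n=2)
        buf = io.StringIO()
        count = view_convert(p, buf)
        text = buf.getvalue()
        assert count == 2
        assert text.startswith("#slow5_version")
        assert r[0].read_id in text


class TestStats:
    def test_counts_match_generator_ground_truth(self, tmp_path):
        cfg = SyntheticConfig(seed=25, n_reads=123, n_read_groups=3,
                              min_signal_len=5, max_signal_len=50)
        header, records = generate_records(cfg)
        p = tmp_path / "s.blow5"
        write_blow5(header, records, p)
        report = stats(p)
        assert report.record_count == 123
        assert report.num_read_groups == 3
        assert sum(report.per_group_counts) == report.record_count
        truth = [0, 0, 0]
        for rec in records:
            truth[rec.read_group] += 1
        assert list(report.per_group_counts) == truth

    def test_empty_file(self, tmp_path, small_dataset):
        header, _ = small_dataset
        p = tmp_path / "e.blow5"
        write_blow5(header, [], p)
        assert stats(p).record_count == 0


class TestQuickcheck:
    def test_valid_file_passes(self, tmp_path):
        p, _, _ = make_run(tmp_path, 26)
        ok, defect = quickcheck(p)
        assert ok and defect is None

    def test_missing_eof_marker(self, tmp_path):
        p, _, _ = make_run(tmp_path, 27)
        bad = tmp_path / "noeof.blow5"
        bad.write_bytes(p.read_bytes()[:-8])
        ok, defect = quickcheck(bad)
        assert not ok and "EOF" in defect

    def test_corrupt_first_frame(self, tmp_path):
        from slow5kit.blow5_format import Blow5Reader

        p, _, _ = make_run(tmp_path, 28)
        with Blow5Reader(p) as reader:
            start = reader.header_end
        data = bytearray(p.read_bytes())
        for i in range(start + 4, start + 12):
            data[i] ^= 0xA5
        bad = tmp_path / "cf.blow5"
        bad.write_bytes(bytes(data))
        ok, defect = quickcheck(bad)
        assert not ok and "record parse failure" in defect


class TestSkim:
    def test_read_ids_match_linear_scan(self, tmp_path):
        p, _, r = make_run(tmp_path, 29, n=30)
        assert skim(p, "read_ids") == [rec.read_id for rec in r]

    def test_header_only_equals_header_lines(self, tmp_path):
        from slow5kit.ascii_format import header_text

        p, h, _ = make_run(tmp_path, 30)
        assert skim(p, "header") == header_text(h).rstrip("\n").split("\n")

    def test_named_columns_parse_back(self, tmp_path):
        p, _, r = make_run(tmp_path, 31)
        lines = skim(p, ["read_id", "len_raw_signal"])
        for line, rec in zip(lines, r):
            rid, n = line.split("\t")
            assert rid == rec.read_id and int(n) == rec.len_raw_signal

    def test_unknown_column_lists_valid_names(self, tmp_path):
        p, _, _ = make_run(tmp_path, 32)
        with pytest.raises(Slow5Error, match="read_id"):
            skim(p, ["nonsense"])


class TestDeterminism:
    def test_rerun_is_byte_identical(self, tmp_path):
        p1, h1, _ = make_run(tmp_path, 33, prefix="runA")
        p2, h2, _ = make_run(tmp_path, 34, prefix="runB")
        outs = []
        for tag in ("x", "y"):
            out = tmp_path / f"m_{tag}.blow5"
            merge([p1, p2], out)
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]
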