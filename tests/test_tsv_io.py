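"""Typed TSV reading/writing, concatenation, compression, split reads."""

import io
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from airr_repkit.errors import (
    CoercionError,
    CompatibilityError,
    HeaderError,
    RenderError,
    RowError,
    UnsupportedOperationError,
)
from airr_repkit.tsv_io import (
    RearrangementRecord,
    coerce_value,
    concat_datasets,
    detect_compression,
    open_source,
    read_from_offset,
    read_metadata,
    read_rearrangements,
    read_segment,
    render_value,
    write_metadata,
    write_rearrangements,
)


class TestCoerce:
    @pytest.mark.parametrize("raw,kind,expected", [
        ("", "integer", None),
        ("", "text", None),
        ("", "boolean", None),
        ("42", "coordinate", 42),
        ("-3", "integer", -3),
        ("62.5", "number", 62.5),
        ("T", "boolean", True),
        ("false", "boolean", False),
        ("ACGT", "nt_sequence", "ACGT"),
        ("AC.T", "gapped_nt_sequence", "AC-T"),  # '.' is a gap synonym
    ])
    def test_values(self, raw, kind, expected):
        assert coerce_value(raw, kind) == expected

    @pytest.mark.parametrize("raw,kind", [
        ("0", "coordinate"),      # coordinates are 1-based
        ("-1", "coordinate"),
        ("1.5", "integer"),
        ("abc", "number"),
        ("nan", "number"),
        ("yes", "boolean"),
    ])
    def test_rejections(self, raw, kind):
        with pytest.raises(CoercionError):
            coerce_value(raw, kind)

    @settings(max_examples=200, derandomize=True)
    @given(st.one_of(
        st.tuples(st.just("integer"), st.integers(-10**9, 10**9)),
        st.tuples(st.just("coordinate"), st.integers(1, 10**9)),
        st.tuples(st.just("number"), st.floats(allow_nan=False, allow_infinity=False)),
        st.tuples(st.just("boolean"), st.booleans()),
        st.tuples(st.just("text"), st.text(
            alphabet=st.characters(blacklist_characters="\t\n\r"), max_size=30)),
    ))
    def test_render_coerce_round_trip(self, pair):
        kind, value = pair
        if value == "":
            value = None  # empty text is indistinguishable from null on disk
        assert coerce_value(render_value(value, kind), kind) == value

    def test_render_rejects_embedded_tab(self):
        with pytest.raises(RenderError):
            render_value("a\tb", "text")


def small_tsv(text: str) -> io.StringIO:
    return io.StringIO(text)


class TestRead:
    def test_small_file_with_custom_and_missing_columns(self, schema):
        src = small_tsv("sequence_id\tsequence\tjunction\tlab_tag\n"
                        "r1\tACGT\tTGTTGG\tx\n"
                        "r2\tCCCC\t\t\n")
        report, records = read_rearrangements(src, schema, strictness="lenient")
        records = list(records)
        assert len(records) == 2
        assert "junction_aa" in report.missing_required
        assert report.custom_columns == ("lab_tag",)
        assert records[0].custom["lab_tag"] == "x"
        assert records[1].values["junction"] is None  # empty string is null
        assert records[1].custom["lab_tag"] is None
        # every declared field has an entry
        assert set(records[0].values) == set(schema.field_names)

    def test_strict_missing_required_aborts(self, schema):
        with pytest.raises(HeaderError, match="required"):
            read_rearrangements(small_tsv("sequence_id\nr1\n"), schema, "strict")

    def test_duplicate_header_rejected(self, schema):
        with pytest.raises(HeaderError, match="duplicate"):
            read_rearrangements(small_tsv("sequence_id\tsequence_id\n"), schema, "lenient")

    def test_wrong_cell_count(self, schema):
        src = small_tsv("sequence_id\tsequence\nr1\tACGT\textra\n")
        report, records = read_rearrangements(src, schema, "lenient")
        assert list(records) == []
        assert report.issues and report.issues[0]["rule"] == "ROW_SHAPE"
        header = "\t".join(schema.field_names)
        bad_row = "\t".join(["x"] * (len(schema.field_names) + 1))
        src = small_tsv(f"{header}\n{bad_row}\n")
        _, records = read_rearrangements(src, schema, "strict")
        with pytest.raises(RowError):
            list(records)

    def test_any_column_order_accepted(self, schema):
        src = small_tsv("sequence\tsequence_id\nACGT\tr1\n")
        _, records = read_rearrangements(src, schema, "lenient")
        rec = next(records)
        assert rec["sequence_id"] == "r1"
        assert rec["sequence"] == "ACGT"


class TestWrite:
    def test_canonical_order_and_custom_last(self, schema):
        rec = RearrangementRecord(values={n: None for n in schema.field_names},
                                  custom={"lab_tag": "x"})
        rec.values["sequence_id"] = "r1"
        buf = io.StringIO()
        assert write_rearrangements([rec], buf, schema) == 1
        header, row = buf.getvalue().splitlines()
        assert header.split("\t") == list(schema.field_names) + ["lab_tag"]
        assert row.split("\t")[0] == "r1"
        # null v_call renders as an empty cell
        assert row.split("\t")[schema.field_names.index("v_call")] == ""

    def test_write_read_write_byte_identity(self, sim_file, schema):
        body = sim_file.read_text()
        _, records = read_rearrangements(sim_file, schema)
        buf = io.StringIO()
        write_rearrangements(list(records), buf, schema)
        assert buf.getvalue() == body

    def test_read_write_read_field_identity(self, sim_file, schema, tmp_path):
        _, records = read_rearrangements(sim_file, schema)
        records = list(records)
        out = tmp_path / "copy.tsv"
        write_rearrangements(records, out, schema)
        _, again = read_rearrangements(out, schema)
        assert list(again) == records

    def test_bad_value_names_record_and_field(self, schema):
        rec = RearrangementRecord(values={n: None for n in schema.field_names})
        rec.values["duplicate_count"] = "lots"
        with pytest.raises(RenderError, match="record 0.*duplicate_count"):
            write_rearrangements([rec], io.StringIO(), schema)


class TestConcat:
    def write(self, tmp_path, name, n, truths, schema, custom=None):
        records = [t.record.copy() for t in truths[:n]]
        if custom:
            for rec in records:
                rec.custom[custom] = "v"
        path = tmp_path / name
        write_rearrangements(records, path, schema)
        return path

    def test_in_order_concatenation_and_union_fill(self, tmp_path, truths200, schema):
        a = self.write(tmp_path, "a.tsv", 10, truths200, schema, custom="x")
        b = self.write(tmp_path, "b.tsv", 5, truths200, schema)
        handle = concat_datasets([a, b], schema)
        records = list(handle.iter_records())
        assert len(records) == 15
        assert records[0].custom["x"] == "v"
        assert all(r.custom["x"] is None for r in records[10:])

    def test_associativity(self, tmp_path, truths200, schema):
        a = self.write(tmp_path, "a.tsv", 4, truths200, schema)
        b = self.write(tmp_path, "b.tsv", 3, truths200, schema)
        c = self.write(tmp_path, "c.tsv", 2, truths200, schema)
        nested = concat_datasets([concat_datasets([a, b], schema), c], schema)
        flat = concat_datasets([a, b, c], schema)
        assert list(nested.iter_records()) == list(flat.iter_records())

    def test_required_column_mismatch_rejected(self, tmp_path, truths200, schema):
        a = self.write(tmp_path, "a.tsv", 2, truths200, schema)
        (tmp_path / "bad.tsv").write_text("sequence_id\tsequence\nr\tACGT\n")
        with pytest.raises(CompatibilityError, match="junction"):
            concat_datasets([a, tmp_path / "bad.tsv"], schema)

    def test_metadata_sidecar_attached(self, tmp_path, truths200, schema):
        a = self.write(tmp_path, "a.tsv", 2, truths200, schema)
        write_metadata({"study": {"id": "S1"}}, tmp_path / "a.yaml")
        handle = concat_datasets([a], schema)
        assert handle.metadata == {"study": {"id": "S1"}}
        assert read_metadata(tmp_path / "a.yaml") == handle.metadata


class TestCompression:
    @pytest.mark.parametrize("suffix,label,splittable", [
        (".tsv", "plain", True),
        (".gz", "gzip", False),
        (".bz2", "bzip2", True),
        (".bgz", "bgzf", True),
    ])
    def test_labels_and_transparent_read(self, tmp_path, truths200, schema,
                                         suffix, label, splittable):
        path = tmp_path / f"d{suffix}"
        write_rearrangements([t.record for t in truths200[:20]], path, schema)
        assert detect_compression(path) == label
        src = open_source(path)
        assert src.compression == label
        assert src.splittable is splittable
        src.close()
        _, records = read_rearrangements(path, schema)
        assert len(list(records)) == 20


class TestSplitReads:
    def test_offset_inside_row_skips_to_next_boundary(self, tmp_path, truths200, schema):
        path = tmp_path / "five.tsv"
        write_rearrangements([t.record for t in truths200[:5]], path, schema)
        text = path.read_bytes()
        # find the byte offset of the middle of row 3 (line index 3 incl. header)
        lines = text.split(b"\n")
        offset = sum(len(l) + 1 for l in lines[:3]) + len(lines[3]) // 2
        got = [r["sequence_id"] for r in read_from_offset(path, offset, schema)]
        assert got == [t.record["sequence_id"] for t in truths200[3:5]]

    def test_offset_at_file_length_is_empty(self, tmp_path, truths200, schema):
        path = tmp_path / "five.tsv"
        write_rearrangements([t.record for t in truths200[:5]], path, schema)
        assert list(read_from_offset(path, path.stat().st_size, schema)) == []

    def test_offset_zero_skips_header_only(self, sim_file, schema):
        first = next(read_from_offset(sim_file, 0, schema))
        assert first["sequence_id"] == "sim-000000"

    @pytest.mark.parametrize("suffix", [".tsv", ".bgz"])
    def test_partitions_reproduce_sequential_read(self, tmp_path, truths200, schema,
                                                  suffix):
        path = tmp_path / f"part{suffix}"
        write_rearrangements([t.record for t in truths200], path, schema)
        sequential = [rec for _, rec in read_segment(path, 0, None, schema)]
        assert len(sequential) == 200
        size = path.stat().st_size
        rng = np.random.default_rng(11)
        for _ in range(8):
            cuts = sorted(set(rng.integers(1, size, size=7).tolist()))
            offsets = [0] + cuts + [size]
            got = list(itertools.chain.from_iterable(
                (rec for _, rec in read_segment(path, a, b, schema))
                for a, b in zip(offsets, offsets[1:])))
            assert got == sequential

    def test_gzip_raises_unsupported(self, tmp_path, truths200, schema):
        path = tmp_path / "d.gz"
        write_rearrangements([t.record for t in truths200[:5]], path, schema)
        with pytest.raises(UnsupportedOperationError, match="splittable"):
            list(read_from_offset(path, 0, schema))
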