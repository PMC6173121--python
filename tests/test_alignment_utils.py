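"""CIGAR/BTOP algebra and coordinate-convention transforms."""

import pytest
from hypothesis import given, settings, strategies as st

from airr_repkit.alignment_utils import (
    CigarOp,
    GappedAlignment,
    Interval,
    aligned_spans,
    btop_to_cigar,
    build_cigar_from_gapped,
    cigar_to_string,
    end_from_length,
    internal_to_interval,
    interval_to_internal,
    length_from_end,
    parse_cigar,
    reconstruct_alignment,
    spans,
)
from airr_repkit.errors import BtopError, CigarError


class TestParseCigar:
    @pytest.mark.parametrize("text,expected", [
        ("10M", [("M", 10)]),
        ("5M5M", [("M", 10)]),  # canonical merge of adjacent equal ops
        ("3M1D4M2I1M", [("M", 3), ("D", 1), ("M", 4), ("I", 2), ("M", 1)]),
        ("2S5M3N1M", [("S", 2), ("M", 5), ("N", 3), ("M", 1)]),
        ("4=1X2=", [("=", 4), ("X", 1), ("=", 2)]),
    ])
    def test_parse(self, text, expected):
        assert parse_cigar(text) == [CigarOp(op, n) for op, n in expected]

    @pytest.mark.parametrize("bad", ["", "M", "0M", "3Q", "3M4", "M3", "3m"])
    def test_malformed_rejected_with_position(self, bad):
        with pytest.raises(CigarError) as exc:
            parse_cigar(bad)
        assert exc.value.position is not None

    def test_string_round_trip(self):
        ops = parse_cigar("2S3M1I2M5N1M4S")
        assert parse_cigar(cigar_to_string(ops)) == ops


class TestSpans:
    @pytest.mark.parametrize("ops,expected", [
        ([("M", 7)], (7, 7)),
        ([("S", 2), ("M", 5)], (7, 5)),
        ([("N", 100), ("M", 3)], (3, 103)),
        ([("M", 3), ("D", 1), ("M", 4), ("I", 2), ("M", 1)], (10, 9)),
    ])
    def test_consumption_table(self, ops, expected):
        assert spans([CigarOp(o, n) for o, n in ops]) == expected

    def test_aligned_spans_exclude_clip_and_skip(self):
        ops = parse_cigar("2S5M1I3M10N4S")
        assert spans(ops) == (15, 18)
        assert aligned_spans(ops) == (9, 8)


class TestReconstruct:
    def test_identity(self):
        aln = reconstruct_alignment("ACGT", "ACGT", parse_cigar("4M"), 1, 1)
        assert (aln.aligned_query, aln.aligned_ref) == ("ACGT", "ACGT")
        assert aln.query_interval == Interval(1, 4)
        assert aln.ref_interval == Interval(1, 4)

    def test_insertion_emits_ref_gap(self):
        aln = reconstruct_alignment("ACGGT", "ACT", parse_cigar("2M2I1M"), 1, 1)
        assert (aln.aligned_query, aln.aligned_ref) == ("ACGGT", "AC--T")

    def test_soft_clip_consumes_query_without_columns(self):
        aln = reconstruct_alignment("TTACG", "ACG", parse_cigar("2S3M"), 1, 1)
        assert (aln.aligned_query, aln.aligned_ref) == ("ACG", "ACG")
        assert aln.query_interval == Interval(3, 5)

    def test_overflow_is_a_bounds_error(self):
        with pytest.raises(CigarError):
            reconstruct_alignment("ACGT", "AC", parse_cigar("4M"), 1, 1)


class TestBuildCigar:
    @pytest.mark.parametrize("q,r,mode,expected", [
        ("ACGT", "ACGT", "M", "4M"),
        ("ACGT", "ACTT", "=X", "2=1X1="),
        ("AC-T", "ACGT", "M", "2M1D1M"),
        ("ACGT", "AC-T", "M", "2M1I1M"),
    ])
    def test_column_classification(self, q, r, mode, expected):
        assert cigar_to_string(build_cigar_from_gapped(q, r, mode)) == expected

    def test_double_gap_column_rejected(self):
        with pytest.raises(CigarError):
            build_cigar_from_gapped("A-C", "A-C")

    def test_gapped_alignment_rejects_double_gap(self):
        with pytest.raises(ValueError):
            GappedAlignment("A-C", "A-C", Interval(1, 2), Interval(1, 2))


# random canonical =X-style alignments: op runs with consistent sequences
@st.composite
def gapped_alignment(draw):
    n_ops = draw(st.integers(1, 12))
    kinds = []
    previous = None
    for _ in range(n_ops):
        op = draw(st.sampled_from("=XID").filter(lambda o: o != previous))
        previous = op
        kinds.append((op, draw(st.integers(1, 6))))
    if all(op in ("I", "D") for op, _ in kinds):
        kinds.append(("=", 1))
    query, ref = [], []
    for op, length in kinds:
        for _ in range(length):
            if op == "=":
                c = draw(st.sampled_from("ACGT"))
                query.append(c)
                ref.append(c)
            elif op == "X":
                c = draw(st.sampled_from("ACGT"))
                d = draw(st.sampled_from([b for b in "ACGT" if b != c]))
                query.append(c)
                ref.append(d)
            elif op == "I":
                query.append(draw(st.sampled_from("ACGT")))
                ref.append("-")
            else:
                query.append("-")
                ref.append(draw(st.sampled_from("ACGT")))
    return "".join(query), "".join(ref)


class TestInversePair:
    @settings(max_examples=200, derandomize=True)
    @given(gapped_alignment())
    def test_build_then_reconstruct_is_identity(self, pair):
        aq, ar = pair
        ops = build_cigar_from_gapped(aq, ar, mode="=X")
        q = aq.replace("-", "")
        r = ar.replace("-", "")
        aln = reconstruct_alignment(q, r, ops, 1, 1)
        assert (aln.aligned_query, aln.aligned_ref) == (aq, ar)
        assert build_cigar_from_gapped(aln.aligned_query, aln.aligned_ref, "=X") == ops
        # M-style collapses = and X into M but leaves gap ops alone
        m_ops = build_cigar_from_gapped(aq, ar, mode="M")
        assert [op for op in m_ops if op.op in "ID"] == [op for op in ops if op.op in "ID"]
        assert spans(m_ops) == spans(ops)

    @settings(max_examples=200, derandomize=True)
    @given(gapped_alignment())
    def test_spans_equal_ungapped_row_lengths(self, pair):
        aq, ar = pair
        ops = build_cigar_from_gapped(aq, ar, mode="=X")
        assert spans(ops) == (len(aq.replace("-", "")), len(ar.replace("-", "")))


class TestBtop:
    @pytest.mark.parametrize("btop,mode,expected", [
        ("46", "M", "46M"),
        ("7AG38", "M", "46M"),
        ("7AG38", "=X", "7=1X38="),
        ("4C-3-A2", "M", "4M1I3M1D2M"),
        ("AGCT", "M", "2M"),      # two mismatch pairs
        ("1A-0-G1", "M", "1M1I1D1M"),  # '0' separates adjacent pairs
    ])
    def test_examples(self, btop, mode, expected):
        assert cigar_to_string(btop_to_cigar(btop, mode)) == expected

    @pytest.mark.parametrize("bad", ["", "A", "4C", "--", "4--2", "4C-3-A2X"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(BtopError):
            btop_to_cigar(bad)


# BTOP token stream with its own independent expansion to aligned rows
@st.composite
def btop_tokens(draw):
    n = draw(st.integers(1, 10))
    tokens = []
    for _ in range(n):
        kind = draw(st.sampled_from(["match", "mismatch", "ins", "del"]))
        if kind == "match":
            tokens.append(draw(st.integers(1, 40)))
        elif kind == "mismatch":
            q = draw(st.sampled_from("ACGT"))
            r = draw(st.sampled_from([b for b in "ACGT" if b != q]))
            tokens.append((q, r))
        elif kind == "ins":
            tokens.append((draw(st.sampled_from("ACGT")), "-"))
        else:
            tokens.append(("-", draw(st.sampled_from("ACGT"))))
    return tokens


def expand_btop_tokens(tokens):
    """Independent oracle: token stream -> aligned placeholder rows."""
    q_row, r_row = [], []
    for tok in tokens:
        if isinstance(tok, int):
            q_row.append("A" * tok)
            r_row.append("A" * tok)
        else:
            q_row.append(tok[0])
            r_row.append(tok[1])
    return "".join(q_row), "".join(r_row)


def render_btop_tokens(tokens):
    # adjacent match runs must be summed: "1" + "1" would read as 11 matches
    merged = []
    for tok in tokens:
        if isinstance(tok, int) and merged and isinstance(merged[-1], int):
            merged[-1] += tok
        else:
            merged.append(tok)
    out = []
    prev_pair = False
    for tok in merged:
        if isinstance(tok, int):
            out.append(str(tok))
            prev_pair = False
        else:
            if prev_pair:
                out.append("0")  # BLAST's separator between adjacent pairs
            out.append(tok[0] + tok[1])
            prev_pair = True
    return "".join(out)


class TestBtopOracle:
    @settings(max_examples=300, derandomize=True)
    @given(btop_tokens())
    def test_agrees_with_expansion_oracle(self, tokens):
        btop = render_btop_tokens(tokens)
        aq, ar = expand_btop_tokens(tokens)
        for mode in ("M", "=X"):
            assert btop_to_cigar(btop, mode) == build_cigar_from_gapped(aq, ar, mode)


class TestCoordinates:
    @pytest.mark.parametrize("iv,expected", [
        (Interval(1, 10), (0, 10)),
        (Interval(5, 5), (4, 5)),
    ])
    def test_to_internal(self, iv, expected):
        assert interval_to_internal(iv) == expected
        assert iv.length == expected[1] - expected[0]

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(1, 10**6), st.integers(0, 10**4))
    def test_bijection(self, start, extent):
        iv = Interval(start, start + extent)
        lo, hi = interval_to_internal(iv)
        assert internal_to_interval(lo, hi) == iv
        assert iv.length == hi - lo == iv.end - iv.start + 1

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            Interval(5, 4)
        with pytest.raises(ValueError):
            Interval(0, 4)

    @pytest.mark.parametrize("start,length,expected", [
        (1, 10, 10), (21, 1, 21), (7, 0, None),
    ])
    def test_end_from_length(self, start, length, expected):
        assert end_from_length(start, length) == expected

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            end_from_length(3, -1)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(1, 10**6), st.integers(0, 10**4))
    def test_end_length_inverse_pair(self, start, length):
        end = end_from_length(start, length)
        assert length_from_end(start, end) == length
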