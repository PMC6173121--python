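"""Alignment-encoding algebra: CIGAR, BTOP, gapped alignments, coordinates.

All genomic-style coordinates in this package are 1-based closed intervals
(both endpoints included), the convention shared by SAM, VCF, GFF, IMGT and
the INSDC formats.  Python-side slicing uses 0-based half-open pairs; the
two are related by the bijection implemented in :func:`interval_to_internal`
and :func:`internal_to_interval`.

CIGAR operator vocabulary and consumption table::

    op   consumes query   consumes reference
    M         yes               yes          (match or mismatch)
    =         yes               yes          (match)
    X         yes               yes          (mismatch)
    I         yes               no           (insertion in query)
    D         no                yes          (deletion from query)
    S         yes               no           (soft clip; no alignment column)
    N         no                yes          (skipped reference stretch)

BTOP (BLAST traceback operations) is the compact legacy encoding this
package converts *from*: runs of digits count matches, two-letter pairs
give (query char, reference char) for a mismatch, and a ``-`` in either
slot of a pair marks a gap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple

from .errors import BtopError, CigarError

CIGAR_OPS = "M=XIDSN"
QUERY_CONSUMING = frozenset("M=XIS")
REF_CONSUMING = frozenset("M=XDN")
#: ops that emit alignment columns (S and N do not)
COLUMN_EMITTING = frozenset("M=XID")
#: ops contributing to the *aligned* span (clip/skip excluded)
ALIGNED_QUERY = frozenset("M=XI")
ALIGNED_REF = frozenset("M=XD")

GAP = "-"

CigarMode = Literal["M", "=X"]


class CigarOp(NamedTuple):
    """One run-length CIGAR operation."""

    op: str
    length: int


_CIGAR_TOKEN = re.compile(r"(\d+)([A-Za-z=])")


def canonicalize(ops: Iterable[CigarOp]) -> list[CigarOp]:
    """Merge adjacent equal operators and validate lengths.

    Raises :class:`CigarError` on zero/negative lengths or unknown ops.
    """
    out: list[CigarOp] = []
    for op, length in ops:
        if op not in CIGAR_OPS:
            raise CigarError(f"unknown CIGAR operator {op!r}")
        if length < 1:
            raise CigarError(f"non-positive CIGAR length {length} for op {op!r}")
        if out and out[-1].op == op:
            out[-1] = CigarOp(op, out[-1].length + length)
        else:
            out.append(CigarOp(op, length))
    return out


def parse_cigar(text: str) -> list[CigarOp]:
    """Parse CIGAR text into a canonical (adjacent-merged) op list.

    Rejects empty input, zero lengths, unknown operator letters and any
    stray characters, reporting the byte position of the offence.
    """
    if not text:
        raise CigarError("empty CIGAR text", position=0)
    ops: list[CigarOp] = []
    pos = 0
    for m in _CIGAR_TOKEN.finditer(text):
        if m.start() != pos:
            raise CigarError(f"malformed CIGAR at byte {pos}: {text[pos:]!r}", position=pos)
        length, op = int(m.group(1)), m.group(2)
        if op not in CIGAR_OPS:
            raise CigarError(f"unknown CIGAR operator {op!r} at byte {m.start(2)}",
                             position=m.start(2))
        if length == 0:
            raise CigarError(f"zero-length CIGAR op at byte {m.start()}", position=m.start())
        ops.append(CigarOp(op, length))
        pos = m.end()
    if pos != len(text):
        raise CigarError(f"malformed CIGAR at byte {pos}: {text[pos:]!r}", position=pos)
    return canonicalize(ops)


def cigar_to_string(ops: Iterable[CigarOp]) -> str:
    return "".join(f"{length}{op}" for op, length in ops)


def spans(ops: Iterable[CigarOp]) -> tuple[int, int]:
    """Total (query, reference) consumption of an op list.

    Counts every consuming op, including soft clips (S, query side) and
    reference skips (N, reference side).
    """
    q = r = 0
    for op, length in ops:
        if op in QUERY_CONSUMING:
            q += length
        if op in REF_CONSUMING:
            r += length
    return q, r


def aligned_spans(ops: Iterable[CigarOp]) -> tuple[int, int]:
    """(query, reference) span of the aligned portion only.

    Excludes S on the query side and N on the reference side, i.e. the
    spans that 1-based closed ``*_start``/``*_end`` annotation intervals
    describe.
    """
    q = r = 0
    for op, length in ops:
        if op in ALIGNED_QUERY:
            q += length
        if op in ALIGNED_REF:
            r += length
    return q, r


@dataclass(frozen=True)
class Interval:
    """1-based closed coordinate interval; ``1 <= start <= end``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid 1-based closed interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def interval_to_internal(iv: Interval) -> tuple[int, int]:
    """1-based closed -> 0-based half-open. Length is preserved."""
    return iv.start - 1, iv.end


def internal_to_interval(lo: int, hi: int) -> Interval:
    """0-based half-open -> 1-based closed. Inverse of :func:`interval_to_internal`."""
    return Interval(lo + 1, hi)


def end_from_length(start: int, length: int) -> int | None:
    """Closed-interval end from a start and a feature length.

    A zero-length feature has no closed interval, hence ``None``.
    """
    if start < 1:
        raise ValueError(f"start must be >= 1, got {start}")
    if length < 0:
        raise ValueError(f"negative length {length}")
    if length == 0:
        return None
    return start + length - 1


def length_from_end(start: int, end: int | None) -> int:
    """Inverse of :func:`end_from_length`; ``None`` end means length 0."""
    if end is None:
        return 0
    return Interval(start, end).length


@dataclass(frozen=True)
class GappedAlignment:
    """An expanded pairwise alignment: two equal-length rows over nt + gap.

    ``query_interval`` / ``ref_interval`` are the 1-based closed spans of
    the ungapped rows within their source sequences.
    """

    aligned_query: str
    aligned_ref: str
    query_interval: Interval
    ref_interval: Interval

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("aligned rows differ in length")
        for i, (a, b) in enumerate(zip(self.aligned_query, self.aligned_ref)):
            if a == GAP and b == GAP:
                raise ValueError(f"double-gap column at {i}")
        if len(self.aligned_query.replace(GAP, "")) != self.query_interval.length:
            raise ValueError("ungapped query row does not match query_interval length")
        if len(self.aligned_ref.replace(GAP, "")) != self.ref_interval.length:
            raise ValueError("ungapped reference row does not match ref_interval length")


def normalize_gaps(aligned: str) -> str:
    """Accept '.' as a gap synonym on input, canonical '-' out."""
    return aligned.replace(".", GAP)


def reconstruct_alignment(query: str, ref: str, ops: Iterable[CigarOp],
                          q_start: int = 1, r_start: int = 1) -> GappedAlignment:
    """Expand a CIGAR into the two aligned rows it describes.

    ``q_start``/``r_start`` are the 1-based positions of the first
    consumed query/reference nucleotide.  I emits a gap in the reference
    row, D and N a gap in the query row; S consumes query without
    emitting columns.  The reported intervals cover the column-emitting
    (aligned) consumption only.
    """
    ops = canonicalize(ops)
    qi = q_start - 1  # 0-based cursor
    ri = r_start - 1
    if qi < 0 or ri < 0:
        raise CigarError("start coordinates must be >= 1")
    rows_q: list[str] = []
    rows_r: list[str] = []
    aq_lo = aq_hi = None  # aligned query 0-based half-open bounds
    ar_lo = ar_hi = None
    for idx, (op, length) in enumerate(ops):
        if op in ("M", "=", "X"):
            if qi + length > len(query) or ri + length > len(ref):
                raise CigarError(f"op {idx} ({length}{op}) overruns a sequence", position=idx)
            rows_q.append(query[qi:qi + length])
            rows_r.append(ref[ri:ri + length])
            if aq_lo is None:
                aq_lo = qi
            if ar_lo is None:
                ar_lo = ri
            qi += length
            ri += length
            aq_hi, ar_hi = qi, ri
        elif op == "I":
            if qi + length > len(query):
                raise CigarError(f"op {idx} ({length}I) overruns the query", position=idx)
            rows_q.append(query[qi:qi + length])
            rows_r.append(GAP * length)
            if aq_lo is None:
                aq_lo = qi
            qi += length
            aq_hi = qi
        elif op in ("D", "N"):
            if ri + length > len(ref):
                raise CigarError(f"op {idx} ({length}{op}) overruns the reference", position=idx)
            rows_q.append(GAP * length)
            rows_r.append(ref[ri:ri + length])
            if op == "D":
                if ar_lo is None:
                    ar_lo = ri
                ar_hi = ri + length
            ri += length
        elif op == "S":
            if qi + length > len(query):
                raise CigarError(f"op {idx} ({length}S) overruns the query", position=idx)
            qi += length
        else:  # pragma: no cover - canonicalize already rejects
            raise CigarError(f"unknown op {op!r}")
    if aq_lo is None or ar_lo is None:
        raise CigarError("CIGAR emits no aligned columns")
    return GappedAlignment(
        aligned_query="".join(rows_q),
        aligned_ref="".join(rows_r),
        query_interval=internal_to_interval(aq_lo, aq_hi),
        ref_interval=internal_to_interval(ar_lo, ar_hi),
    )


def build_cigar_from_gapped(aligned_query: str, aligned_ref: str,
                            mode: CigarMode = "M") -> list[CigarOp]:
    """Column-classify an expanded alignment back into canonical ops.

    ``mode='M'`` merges match and mismatch into M; ``mode='=X'`` keeps
    them distinct.  A column with gaps in both rows is structurally
    invalid.
    """
    if len(aligned_query) != len(aligned_ref):
        raise CigarError("aligned rows differ in length")
    if mode not in ("M", "=X"):
        raise ValueError(f"unknown CIGAR mode {mode!r}")
    ops: list[CigarOp] = []
    for i, (a, b) in enumerate(zip(aligned_query, aligned_ref)):
        if a == GAP and b == GAP:
            raise CigarError(f"double-gap column at {i}", position=i)
        if b == GAP:
            op = "I"
        elif a == GAP:
            op = "D"
        elif mode == "M":
            op = "M"
        else:
            op = "=" if a == b else "X"
        ops.append(CigarOp(op, 1))
    return canonicalize(ops)


_BTOP_TOKEN = re.compile(r"(\d+)|([A-Za-z-]{2})")


def btop_to_cigar(btop: str, mode: CigarMode = "M") -> list[CigarOp]:
    """Convert a BLAST traceback (BTOP) string into canonical CIGAR ops.

    Digit runs become M (or =) runs; a two-character pair becomes 1M/1X
    (mismatch), 1I (query char over ``-``) or 1D (``-`` over reference
    char).  ``--`` pairs and dangling single letters are rejected.
    """
    if not btop:
        raise BtopError("empty BTOP text", position=0)
    if mode not in ("M", "=X"):
        raise ValueError(f"unknown CIGAR mode {mode!r}")
    match_op = "M" if mode == "M" else "="
    mismatch_op = "M" if mode == "M" else "X"
    ops: list[CigarOp] = []
    pos = 0
    for m in _BTOP_TOKEN.finditer(btop):
        if m.start() != pos:
            raise BtopError(f"malformed BTOP at byte {pos}: {btop[pos:]!r}", position=pos)
        if m.group(1) is not None:
            n = int(m.group(1))
            if n > 0:  # "0" is a legal BLAST separator between adjacent pairs
                ops.append(CigarOp(match_op, n))
        else:
            q, r = m.group(2)
            if q == "-" and r == "-":
                raise BtopError(f"'--' pair at byte {m.start()}", position=m.start())
            if q == "-":
                ops.append(CigarOp("D", 1))
            elif r == "-":
                ops.append(CigarOp("I", 1))
            else:
                ops.append(CigarOp(mismatch_op, 1))
        pos = m.end()
    if pos != len(btop):
        raise BtopError(f"dangling BTOP text at byte {pos}: {btop[pos:]!r}", position=pos)
    if not ops:
        raise BtopError("BTOP encodes no columns", position=0)
    return canonicalize(ops)
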