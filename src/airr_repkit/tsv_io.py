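"""Read/write machinery for Rearrangement TSV files.

Dialect (deliberately minimal, so a newline is always a record boundary
and files stay splittable):

* UTF-8; tab-separated; no quoting and no escaping — tab and newline are
  forbidden inside values and rejected at write time;
* mandatory single header row of unique column names; no comment or
  meta-information section;
* null is the empty string, for every field including required ones;
* readers accept any column order, writers always emit the canonical
  schema order followed by custom columns in first-seen order;
* line terminator ``\\n`` on write, ``\\r\\n`` tolerated on read.

Compression containers are detected from magic bytes, not file names:
plain, gzip, bzip2 and BGZF (blocked gzip) are read transparently.
Only plain and BGZF sources support reading from an arbitrary byte
offset; standard gzip is not splittable.
"""

from __future__ import annotations

import bz2
import gzip
import io
import math
import os
import tempfile
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import yaml
from Bio import bgzf

from .alignment_utils import normalize_gaps
from .errors import (
    CoercionError,
    CompatibilityError,
    HeaderError,
    RenderError,
    RowError,
    UnsupportedOperationError,
)
from .schema_model import FieldSpec, RearrangementSchema, default_schema

_BOOL_TRUE = frozenset({"T", "TRUE", "true"})
_BOOL_FALSE = frozenset({"F", "FALSE", "false"})


def coerce_value(raw: str, kind: str, *, field: str | None = None):
    """Parse one TSV cell according to its value kind.

    The empty string is null for every kind.  Coordinates must be
    integers >= 1 (1-based closed convention).  Booleans accept the
    spellings T/TRUE/true/F/FALSE/false.  Gapped sequences normalize
    the '.' gap synonym to '-'.
    """
    if raw == "":
        return None
    if kind in ("text", "nt_sequence", "aa_sequence", "cigar_text"):
        return raw
    if kind == "gapped_nt_sequence":
        return normalize_gaps(raw)
    if kind in ("integer", "coordinate"):
        try:
            value = int(raw)
        except ValueError:
            raise CoercionError(f"cannot parse {raw!r} as {kind}", kind=kind, text=raw,
                                field=field) from None
        if kind == "coordinate" and value < 1:
            raise CoercionError(
                f"coordinate must be >= 1 (1-based closed convention), got {raw!r}",
                kind=kind, text=raw, field=field)
        return value
    if kind == "number":
        try:
            value = float(raw)
        except ValueError:
            raise CoercionError(f"cannot parse {raw!r} as number", kind=kind, text=raw,
                                field=field) from None
        if not math.isfinite(value):
            raise CoercionError(f"non-finite number {raw!r}", kind=kind, text=raw, field=field)
        return value
    if kind == "boolean":
        if raw in _BOOL_TRUE:
            return True
        if raw in _BOOL_FALSE:
            return False
        raise CoercionError(f"cannot parse {raw!r} as boolean (use T/TRUE/true/F/FALSE/false)",
                            kind=kind, text=raw, field=field)
    raise ValueError(f"unknown value kind {kind!r}")


def render_value(value, kind: str, *, field: str | None = None) -> str:
    """Inverse of :func:`coerce_value`: typed value -> canonical cell text.

    Null renders as the empty string; booleans as T/F; numbers via the
    shortest round-tripping representation.  Values that do not satisfy
    their kind, or that contain tab/newline, are rejected.
    """
    where = f" in field {field!r}" if field else ""
    if value is None:
        return ""
    if kind == "boolean":
        if not isinstance(value, bool):
            raise RenderError(f"expected boolean{where}, got {value!r}")
        return "T" if value else "F"
    if kind in ("integer", "coordinate"):
        if isinstance(value, bool) or not isinstance(value, int):
            raise RenderError(f"expected {kind}{where}, got {value!r}")
        if kind == "coordinate" and value < 1:
            raise RenderError(f"coordinate{where} must be >= 1, got {value}")
        return str(value)
    if kind == "number":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise RenderError(f"expected number{where}, got {value!r}")
        if not math.isfinite(value):
            raise RenderError(f"non-finite number{where}: {value!r}")
        return str(value) if isinstance(value, int) else repr(float(value))
    if kind in ("text", "nt_sequence", "aa_sequence", "gapped_nt_sequence", "cigar_text"):
        if not isinstance(value, str):
            raise RenderError(f"expected string for {kind}{where}, got {value!r}")
        if "\t" in value or "\n" in value or "\r" in value:
            raise RenderError(f"tab/newline forbidden inside values{where}")
        return value
    raise ValueError(f"unknown value kind {kind!r}")


@dataclass
class RearrangementRecord:
    """One annotated rearrangement: typed schema fields plus custom columns.

    ``values`` maps every declared field name to a typed value or None;
    ``custom`` carries undeclared columns untyped (text or None).
    """

    values: dict = dc_field(default_factory=dict)
    custom: dict = dc_field(default_factory=dict)

    def __getitem__(self, name: str):
        if name in self.values:
            return self.values[name]
        return self.custom[name]

    def get(self, name: str, default=None):
        if name in self.values:
            return self.values[name]
        return self.custom.get(name, default)

    def __contains__(self, name: str) -> bool:
        return name in self.values or name in self.custom

    def copy(self) -> "RearrangementRecord":
        return RearrangementRecord(dict(self.values), dict(self.custom))


@dataclass
class HeaderReport:
    """Outcome of header resolution, plus lenient-mode row issues."""

    columns: tuple[str, ...]
    missing_required: tuple[str, ...]
    missing_declared: tuple[str, ...]
    custom_columns: tuple[str, ...]
    issues: list = dc_field(default_factory=list)


# ---------------------------------------------------------------------------
# compression detection / transparent open
# ---------------------------------------------------------------------------

PLAIN, GZIP, BZIP2, BGZF = "plain", "gzip", "bzip2", "bgzf"
SPLITTABLE_LABELS = frozenset({PLAIN, BZIP2, BGZF})


def detect_compression(path: str | Path) -> str:
    """Sniff the compression container from magic bytes."""
    with open(path, "rb") as fh:
        head = fh.read(18)
    if head.startswith(b"\x42\x5a\x68"):  # 'BZh'
        return BZIP2
    if head.startswith(b"\x1f\x8b"):
        # BGZF is gzip with FEXTRA and a 'BC' subfield carrying the block size
        if len(head) >= 18 and head[3] & 0x04 and head[12:14] == b"BC":
            return BGZF
        return GZIP
    return PLAIN


@dataclass
class SourceStream:
    """A transparently decompressed byte stream plus its container label."""

    handle: IO[bytes]
    compression: str
    path: Path | None = None

    @property
    def splittable(self) -> bool:
        """Whether the container permits reading from arbitrary byte offsets.

        bzip2 is splittable in principle (block-framed); arbitrary-offset
        decoding for it is not implemented here — see
        :func:`read_from_offset`.
        """
        return self.compression in SPLITTABLE_LABELS

    def text(self) -> IO[str]:
        if isinstance(self.handle, io.IOBase) or hasattr(self.handle, "readable"):
            return io.TextIOWrapper(self.handle, encoding="utf-8", newline="")
        return _DecodingReader(self.handle)  # BgzfReader lacks the io ABC

    def close(self) -> None:
        self.handle.close()


class _DecodingReader:
    """Line-oriented text adapter over byte readers outside the io hierarchy."""

    def __init__(self, handle):
        self._handle = handle

    def readline(self) -> str:
        line = self._handle.readline()
        return line.decode("utf-8") if isinstance(line, bytes) else line

    def __iter__(self):
        while True:
            line = self.readline()
            if not line:
                return
            yield line

    def close(self) -> None:
        self._handle.close()


def open_source(path: str | Path) -> SourceStream:
    """Open ``path`` for reading with transparent decompression."""
    path = Path(path)
    label = detect_compression(path)
    if label == GZIP:
        handle: IO[bytes] = gzip.open(path, "rb")
    elif label == BZIP2:
        handle = bz2.open(path, "rb")
    elif label == BGZF:
        handle = bgzf.BgzfReader(str(path), "rb")
    else:
        handle = open(path, "rb")
    return SourceStream(handle=handle, compression=label, path=path)


def _open_sink(path: Path) -> IO[bytes]:
    suffix = path.suffix.lower()
    if suffix in (".bgz", ".bgzf"):
        return bgzf.BgzfWriter(str(path), "wb")
    if suffix == ".gz":
        # mtime pinned so identical input yields identical bytes
        return gzip.GzipFile(filename="", fileobj=open(path, "wb"), mode="wb", mtime=0)
    if suffix == ".bz2":
        return bz2.open(path, "wb")
    return open(path, "wb")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _split_header(line: str) -> list[str]:
    return line.rstrip("\r\n").split("\t")


def resolve_header(columns: Sequence[str], schema: RearrangementSchema,
                   strictness: str = "strict") -> HeaderReport:
    """Check a header against the schema and classify its columns."""
    seen = set()
    for name in columns:
        if name in seen:
            raise HeaderError(f"duplicate column name {name!r} in header")
        seen.add(name)
    missing_required = tuple(n for n in schema.required_names if n not in seen)
    missing_declared = tuple(n for n in schema.field_names if n not in seen)
    custom = tuple(n for n in columns if n not in schema)
    if strictness == "strict" and missing_required:
        raise HeaderError(f"missing required columns: {', '.join(missing_required)}")
    return HeaderReport(columns=tuple(columns), missing_required=missing_required,
                        missing_declared=missing_declared, custom_columns=custom)


def _parse_row(cells: Sequence[str], columns: Sequence[str], schema: RearrangementSchema,
               row_index: int, strictness: str, report: HeaderReport) -> RearrangementRecord | None:
    if len(cells) != len(columns):
        msg = (f"row {row_index}: expected {len(columns)} cells, got {len(cells)}")
        if strictness == "strict":
            raise RowError(msg, row_index=row_index)
        report.issues.append({"rule": "ROW_SHAPE", "row": row_index, "field": None,
                              "message": msg})
        return None
    values = {name: None for name in schema.field_names}
    custom: dict = {name: None for name in report.custom_columns}
    for name, raw in zip(columns, cells):
        spec = schema.get(name)
        if spec is None:
            custom[name] = raw if raw != "" else None
            continue
        try:
            values[name] = coerce_value(raw, spec.value_kind, field=name)
        except CoercionError as exc:
            if strictness == "strict":
                raise RowError(f"row {row_index}: {exc}", row_index=row_index) from exc
            report.issues.append({"rule": "TYPE", "row": row_index, "field": name,
                                  "message": f"row {row_index}: {exc}"})
            values[name] = None
    return RearrangementRecord(values=values, custom=custom)


def read_rearrangements(source, schema: RearrangementSchema | None = None,
                        strictness: str = "strict",
                        ) -> tuple[HeaderReport, Iterator[RearrangementRecord]]:
    """Open a Rearrangement TSV and return (header report, lazy record stream).

    ``source`` may be a path (compressed containers are detected) or a
    text stream.  Records are yielded lazily: the stream is never
    materialized.  In strict mode a missing required column, a wrong
    cell count, or an unparseable cell aborts with an exception; in
    lenient mode these become entries in ``report.issues`` (bad rows are
    skipped, bad cells become null).
    """
    if strictness not in ("strict", "lenient"):
        raise ValueError(f"unknown strictness {strictness!r}")
    if schema is None:
        schema = default_schema()
    owns = False
    if isinstance(source, (str, Path)):
        stream = open_source(source).text()
        owns = True
    else:
        stream = source
    header_line = stream.readline()
    if not header_line.strip():
        if owns:
            stream.close()
        raise HeaderError("empty input: a header row is mandatory")
    columns = _split_header(header_line)
    report = resolve_header(columns, schema, strictness)

    def records() -> Iterator[RearrangementRecord]:
        try:
            row_index = 0
            for line in stream:
                line = line.rstrip("\r\n")
                if line == "":
                    continue
                row_index += 1
                rec = _parse_row(line.split("\t"), columns, schema, row_index,
                                 strictness, report)
                if rec is not None:
                    yield rec
        finally:
            if owns:
                stream.close()

    return report, records()


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def render_record(record: RearrangementRecord, schema: RearrangementSchema,
                  custom_columns: Sequence[str]) -> str:
    cells = [render_value(record.values.get(f.name), f.value_kind, field=f.name)
             for f in schema]
    for name in custom_columns:
        value = record.custom.get(name)
        if value is None:
            cells.append("")
        else:
            text = value if isinstance(value, str) else str(value)
            if "\t" in text or "\n" in text or "\r" in text:
                raise RenderError(f"tab/newline forbidden inside values in custom field {name!r}")
            cells.append(text)
    return "\t".join(cells)


def collect_custom_columns(records: Iterable[RearrangementRecord]) -> list[str]:
    """Custom column names in first-seen order across records."""
    order: list[str] = []
    seen: set[str] = set()
    for rec in records:
        for name in rec.custom:
            if name not in seen:
                seen.add(name)
                order.append(name)
    return order


def write_rearrangements(records: Iterable[RearrangementRecord], sink,
                         schema: RearrangementSchema | None = None) -> int:
    """Write records as a canonical-order Rearrangement TSV; returns row count.

    The header is the schema's canonical column order followed by custom
    columns in first-seen order.  Output is bit-stable for identical
    input.  When ``sink`` is a path the file is written atomically
    (temp file + rename) and a ``.gz``/``.bz2``/``.bgz`` suffix selects
    the compression container.
    """
    if schema is None:
        schema = default_schema()
    records = records if isinstance(records, (list, tuple)) else list(records)
    custom_columns = collect_custom_columns(records)

    def emit(text: IO[str]) -> int:
        text.write("\t".join(list(schema.field_names) + custom_columns) + "\n")
        count = 0
        for i, rec in enumerate(records):
            try:
                text.write(render_record(rec, schema, custom_columns) + "\n")
            except RenderError as exc:
                raise RenderError(f"record {i}: {exc}") from exc
            count += 1
        return count

    if isinstance(sink, (str, Path)):
        path = Path(sink)
        tmp_fd, tmp_name = tempfile.mkstemp(dir=path.parent or Path("."),
                                            prefix=f".{path.name}.", suffix=".tmp")
        os.close(tmp_fd)
        tmp_path = Path(tmp_name)
        try:
            # compression chosen from the *final* suffix, so write through a
            # handle opened under the temp name but framed for the target
            handle = _open_sink_like(path, tmp_path)
            try:
                count = emit(_EncodingWriter(handle))
            finally:
                handle.close()
            os.replace(tmp_path, path)
        except BaseException:
            tmp_path.unlink(missing_ok=True)
            raise
        return count
    return emit(sink)


class _EncodingWriter:
    """Minimal text adapter over byte sinks (BgzfWriter lacks the io ABC)."""

    def __init__(self, handle: IO[bytes]):
        self._handle = handle

    def write(self, text: str) -> int:
        self._handle.write(text.encode("utf-8"))
        return len(text)


def _open_sink_like(final_path: Path, tmp_path: Path) -> IO[bytes]:
    suffix = final_path.suffix.lower()
    if suffix in (".bgz", ".bgzf"):
        return bgzf.BgzfWriter(str(tmp_path), "wb")
    if suffix == ".gz":
        return gzip.GzipFile(filename="", fileobj=open(tmp_path, "wb"), mode="wb", mtime=0)
    if suffix == ".bz2":
        return bz2.open(tmp_path, "wb")
    return open(tmp_path, "wb")


# ---------------------------------------------------------------------------
# dataset concatenation
# ---------------------------------------------------------------------------


@dataclass
class DatasetHandle:
    """An ordered collection of TSV sources treated as one logical dataset."""

    sources: tuple[Path, ...]
    schema: RearrangementSchema
    columns: tuple[str, ...]
    metadata: object | None = None

    def iter_records(self, strictness: str = "strict") -> Iterator[RearrangementRecord]:
        """In-order concatenated record stream with union-filled columns.

        A custom column present in one member but absent in another is
        null in records from the latter.
        """
        custom_union = [c for c in self.columns if c not in self.schema]
        for path in self.sources:
            _, records = read_rearrangements(path, self.schema, strictness)
            for rec in records:
                for name in custom_union:
                    rec.custom.setdefault(name, None)
                yield rec


def _sidecar_path(path: Path) -> Path | None:
    for candidate in (path.with_suffix(".yaml"), Path(str(path) + ".yaml")):
        if candidate != path and candidate.exists():
            return candidate
    return None


def read_metadata(path: str | Path):
    """Load a companion metadata document (opaque YAML structure)."""
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def write_metadata(document, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(document, fh, sort_keys=False)


def concat_datasets(sources: Sequence, schema: RearrangementSchema | None = None,
                    ) -> DatasetHandle:
    """Treat TSV files (or directories, or other handles) as one dataset.

    All members must expose an identical set of schema-required columns;
    the resolved column set is the union, in first-seen order.  The
    record stream is the in-order concatenation.  A YAML sidecar with
    the same basename as the *first* member, if present, is attached as
    companion metadata.
    """
    if schema is None:
        schema = default_schema()
    if not sources:
        raise ValueError("concat_datasets requires at least one source")
    paths: list[Path] = []
    for src in sources:
        if isinstance(src, DatasetHandle):
            paths.extend(src.sources)
            continue
        p = Path(src)
        if p.is_dir():
            members = sorted(q for q in p.iterdir()
                             if q.suffix in (".tsv", ".gz", ".bz2", ".bgz", ".bgzf"))
            if not members:
                raise ValueError(f"directory {p} contains no TSV members")
            paths.extend(members)
        else:
            paths.append(p)

    union: list[str] = []
    seen: set[str] = set()
    required_sets: list[tuple[Path, frozenset[str]]] = []
    for path in paths:
        stream = open_source(path).text()
        try:
            columns = _split_header(stream.readline())
        finally:
            stream.close()
        resolve_header(columns, schema, strictness="lenient")  # reject dup names
        required_sets.append((path, frozenset(c for c in columns if c in set(schema.required_names))))
        for c in columns:
            if c not in seen:
                seen.add(c)
                union.append(c)
    baseline = required_sets[0][1]
    for path, req in required_sets[1:]:
        if req != baseline:
            diff = sorted(baseline.symmetric_difference(req))
            raise CompatibilityError(
                f"{path} does not share the required-column set of {required_sets[0][0]}; "
                f"differing columns: {', '.join(diff)}")
    # declared-but-absent columns are null-filled on read; the resolved union
    # keeps canonical fields first for predictable downstream writes
    ordered = [n for n in schema.field_names if n in seen] + [n for n in union
                                                              if n not in schema]
    metadata = None
    sidecar = _sidecar_path(paths[0])
    if sidecar is not None:
        metadata = read_metadata(sidecar)
    return DatasetHandle(sources=tuple(paths), schema=schema, columns=tuple(ordered),
                         metadata=metadata)


# ---------------------------------------------------------------------------
# splittable access
# ---------------------------------------------------------------------------


def _bgzf_block_starts(raw: bytes) -> list[int]:
    """Offsets of every BGZF block by walking the BC subfield block sizes."""
    starts = []
    pos = 0
    n = len(raw)
    while pos < n:
        if raw[pos:pos + 2] != b"\x1f\x8b" or pos + 18 > n:
            raise UnsupportedOperationError(f"corrupt BGZF framing at byte {pos}")
        if raw[pos + 12:pos + 14] != b"BC":
            raise UnsupportedOperationError(f"missing BGZF 'BC' subfield at byte {pos}")
        bsize = int.from_bytes(raw[pos + 16:pos + 18], "little") + 1
        starts.append(pos)
        pos += bsize
    return starts


def _iter_marked_plain(path: Path, offset: int) -> Iterator[tuple[float, str]]:
    """Yield (record-start byte offset, line text) from the boundary at/after offset.

    A line owned by an offset is one whose first byte is >= offset; a
    line straddling the offset belongs to the preceding region and is
    skipped.  Offset 0 skips the header line.
    """
    size = path.stat().st_size
    if offset >= size:
        return
    with open(path, "rb") as fh:
        if offset == 0:
            fh.readline()  # header
        else:
            fh.seek(offset - 1)
            if fh.read(1) != b"\n":
                fh.readline()  # finish the straddling line; it is not ours
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                return
            yield float(pos), line.decode("utf-8")


def _iter_marked_bgzf(path: Path, offset: int) -> Iterator[tuple[float, str]]:
    """BGZF analogue of :func:`_iter_marked_plain`.

    Offsets are positions in the *compressed* byte stream; a record's
    marker is ``block_start + within_block_offset / 2**16``, derived
    from the reader's virtual offset, so markers interleave correctly
    with raw byte offsets.
    """
    raw = Path(path).read_bytes()
    if offset >= len(raw):
        return
    starts = _bgzf_block_starts(raw)
    reader = bgzf.BgzfReader(str(path), "rb")
    try:
        if offset == 0:
            reader.readline()  # header
        else:
            nxt = [s for s in starts if s >= offset]
            if not nxt:
                return
            b0 = nxt[0]
            prev = max(s for s in starts if s < b0)
            reader.seek(bgzf.make_virtual_offset(b0, 0))
            # the block boundary is a record boundary only if the previous
            # block's decompressed payload ends with a newline
            prev_payload = gzip.decompress(raw[prev:b0])
            if not prev_payload.endswith(b"\n"):
                reader.readline()
        while True:
            voff = reader.tell()
            line = reader.readline()
            if not line:
                return
            coffset, within = bgzf.split_virtual_offset(voff)
            if isinstance(line, bytes):  # Bio.bgzf mode-dependent
                line = line.decode("utf-8")
            yield coffset + within / 65536.0, line
    finally:
        reader.close()


def _marked_lines(path: Path, offset: int) -> Iterator[tuple[float, str]]:
    label = detect_compression(path)
    if label == PLAIN:
        return _iter_marked_plain(path, offset)
    if label == BGZF:
        return _iter_marked_bgzf(path, offset)
    if label == BZIP2:
        raise UnsupportedOperationError(
            "bzip2 sources are splittable in principle, but arbitrary-offset decoding "
            "is not implemented; recompress with BGZF (blocked gzip) for split reads")
    raise UnsupportedOperationError(
        f"{label} compression is not splittable; use plain TSV or a splittable "
        "compression format such as BGZF (blocked gzip) or bzip2")


def _read_header_columns(path: Path) -> list[str]:
    stream = open_source(path).text()
    try:
        return _split_header(stream.readline())
    finally:
        stream.close()


def read_from_offset(path: str | Path, offset: int,
                     schema: RearrangementSchema | None = None,
                     strictness: str = "strict") -> Iterator[RearrangementRecord]:
    """Yield complete records starting at the first record boundary >= offset.

    ``offset`` addresses the on-disk byte stream (compressed bytes for
    BGZF).  Offset 0 skips the header line; an offset inside a record
    skips forward past that record's terminating newline; an offset at
    or beyond end of file yields nothing.  Non-splittable sources raise
    :class:`UnsupportedOperationError`.
    """
    for _, rec in read_segment(Path(path), offset, None, schema, strictness):
        yield rec


def read_segment(path: str | Path, start: int, end: int | None,
                 schema: RearrangementSchema | None = None,
                 strictness: str = "strict",
                 ) -> Iterator[tuple[float, RearrangementRecord]]:
    """Yield (marker, record) for records whose start lies in ``[start, end)``.

    Any partition ``0 = o0 < o1 < ... < ok = file size`` of the on-disk
    byte stream therefore yields, across segments ``[oi, oi+1)``, each
    record exactly once — the split-read contract.  ``end=None`` means
    end of file.
    """
    path = Path(path)
    if schema is None:
        schema = default_schema()
    columns = _read_header_columns(path)
    report = resolve_header(columns, schema, strictness)
    row_index = 0
    for marker, line in _marked_lines(path, start):
        if end is not None and marker >= end:
            return
        line = line.rstrip("\r\n")
        if line == "":
            continue
        row_index += 1
        rec = _parse_row(line.split("\t"), columns, schema, row_index, strictness, report)
        if rec is not None:
            yield marker, rec
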