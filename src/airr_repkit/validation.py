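"""Rule-based validation of headers, records and whole datasets.

Rules are identified by stable ids so reports are machine-readable.
Cross-field rules only fire when every participating field is non-null:
nullability is universal in this standard, so absence is never itself a
record-level error (only header-level requiredness is enforced).

Registered rules
----------------
Header level:

* ``MISSING_REQUIRED`` (error) — a required column is absent from the header.
* ``DUPLICATE_COLUMN`` (warning) — two column names collide after case folding.
* ``SUSPICIOUS_WHITESPACE`` (warning) — a column name carries leading/trailing
  or embedded whitespace.

Record level (errors):

* ``TYPE`` — a value does not satisfy its declared value kind.
* ``INTERVAL`` — a paired ``*_start``/``*_end`` violates 1 <= start <= end.
* ``JUNC_LEN`` — junction_length != len(junction).
* ``JUNC_AA`` — 3 * len(junction_aa) != len(junction).
* ``CIGAR_SPAN`` — a gene CIGAR's aligned query span (S excluded) differs from
  its ``*_sequence_start/_end`` interval, or its aligned reference span
  (N excluded) differs from ``*_germline_start/_end``.
* ``REGION_BOUNDS`` — a region interval falls outside [1, len(sequence)].
* ``ALN_LEN`` — sequence_alignment and germline_alignment differ in length.
* ``ROW_SHAPE`` — a data row with the wrong cell count (dataset-level reads
  only; such rows cannot be typed at all).

Record level (warnings):

* ``IDENTITY_RANGE`` — an ``*_identity`` outside both [0, 1] and [0, 100]
  (these context-dependent fields carry no standardized scale).
* ``ALPHABET`` — characters outside the IUPAC nucleotide codes (plus gaps in
  gapped fields) or outside the amino acid alphabet (20 + X + ``*``).
* ``PRODUCTIVE_CONSISTENCY`` (opt-in strict rule) — productive is True while
  the junction is out of frame or its translation contains a stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Iterator, Sequence

from .alignment_utils import aligned_spans, parse_cigar
from .errors import CigarError
from .schema_model import RearrangementSchema, default_schema
from .tsv_io import DatasetHandle, RearrangementRecord, coerce_value

ERROR, WARNING = "error", "warning"

#: record-level error rules that corruption fixtures can target
RECORD_ERROR_RULES = ("TYPE", "INTERVAL", "JUNC_LEN", "JUNC_AA", "CIGAR_SPAN",
                      "REGION_BOUNDS", "ALN_LEN")

HEADER_RULES = ("MISSING_REQUIRED", "DUPLICATE_COLUMN", "SUSPICIOUS_WHITESPACE")
WARNING_RULES = ("IDENTITY_RANGE", "ALPHABET", "PRODUCTIVE_CONSISTENCY")

ALL_RULES = HEADER_RULES + RECORD_ERROR_RULES + WARNING_RULES

NT_ALPHABET = frozenset("ACGTURYSWKMBDHVN")
GAP_CHARS = frozenset("-.")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")

GENES = ("v", "d", "j", "c")
REGIONS = ("fwr1", "cdr1", "fwr2", "cdr2", "fwr3", "cdr3", "fwr4")


@dataclass(frozen=True)
class ValidationIssue:
    rule_id: str
    severity: str
    message: str
    record_index: int | None = None
    field: str | None = None


@dataclass
class RuleConfig:
    """Which rules run.  ``strict_productive`` opts into the frame/stop check."""

    disabled: frozenset[str] = frozenset()
    strict_productive: bool = False

    def enabled(self, rule_id: str) -> bool:
        if rule_id == "PRODUCTIVE_CONSISTENCY":
            return self.strict_productive and rule_id not in self.disabled
        return rule_id not in self.disabled


@dataclass
class ValidationReport:
    """Aggregated issue counts; ``passed`` iff no error-severity issues."""

    total_records: int = 0
    error_count: int = 0
    warning_count: int = 0
    by_rule: dict = dc_field(default_factory=dict)
    issues: list = dc_field(default_factory=list)
    max_kept_issues: int = 1000

    @property
    def passed(self) -> bool:
        return self.error_count == 0

    def add(self, issue: ValidationIssue) -> None:
        self.by_rule[issue.rule_id] = self.by_rule.get(issue.rule_id, 0) + 1
        if issue.severity == ERROR:
            self.error_count += 1
        else:
            self.warning_count += 1
        if len(self.issues) < self.max_kept_issues:
            self.issues.append(issue)

    def as_dict(self) -> dict:
        return {
            "total_records": self.total_records,
            "error_count": self.error_count,
            "warning_count": self.warning_count,
            "passed": self.passed,
            "by_rule": dict(sorted(self.by_rule.items())),
        }


def validate_header(columns: Sequence[str], schema: RearrangementSchema | None = None,
                    config: RuleConfig | None = None) -> list[ValidationIssue]:
    """Header checks: required presence, case-fold collisions, whitespace."""
    if schema is None:
        schema = default_schema()
    config = config or RuleConfig()
    issues: list[ValidationIssue] = []
    present = set(columns)
    if config.enabled("MISSING_REQUIRED"):
        for name in schema.required_names:
            if name not in present:
                issues.append(ValidationIssue(
                    "MISSING_REQUIRED", ERROR,
                    f"required column {name!r} absent from header", field=name))
    if config.enabled("DUPLICATE_COLUMN"):
        folded: dict[str, str] = {}
        for name in columns:
            key = name.casefold()
            if key in folded and folded[key] != name:
                issues.append(ValidationIssue(
                    "DUPLICATE_COLUMN", WARNING,
                    f"columns {folded[key]!r} and {name!r} collide after case folding",
                    field=name))
            folded.setdefault(key, name)
    if config.enabled("SUSPICIOUS_WHITESPACE"):
        for name in columns:
            if name != name.strip() or any(c.isspace() for c in name):
                issues.append(ValidationIssue(
                    "SUSPICIOUS_WHITESPACE", WARNING,
                    f"column name {name!r} contains whitespace", field=name))
    return issues


def _kind_ok(value, kind: str) -> bool:
    if value is None:
        return True
    if kind == "boolean":
        return isinstance(value, bool)
    if kind in ("integer", "coordinate"):
        if isinstance(value, bool) or not isinstance(value, int):
            return False
        return kind == "integer" or value >= 1
    if kind == "number":
        return not isinstance(value, bool) and isinstance(value, (int, float))
    return isinstance(value, str)


def _interval_pairs(schema: RearrangementSchema) -> list[tuple[str, str]]:
    pairs = []
    for f in schema:
        if f.name.endswith("_start"):
            end = f.name[: -len("_start")] + "_end"
            if end in schema:
                pairs.append((f.name, end))
    return pairs


def validate_record(record: RearrangementRecord, schema: RearrangementSchema | None = None,
                    config: RuleConfig | None = None,
                    record_index: int | None = None) -> list[ValidationIssue]:
    """Apply all record-level rules; returns the (possibly empty) issue list."""
    if schema is None:
        schema = default_schema()
    config = config or RuleConfig()
    issues: list[ValidationIssue] = []

    def err(rule: str, message: str, field: str | None = None) -> None:
        issues.append(ValidationIssue(rule, ERROR, message, record_index, field))

    def warn(rule: str, message: str, field: str | None = None) -> None:
        issues.append(ValidationIssue(rule, WARNING, message, record_index, field))

    get = record.values.get

    if config.enabled("TYPE"):
        for f in schema:
            value = get(f.name)
            if not _kind_ok(value, f.value_kind):
                err("TYPE", f"{f.name}={value!r} does not satisfy kind {f.value_kind}", f.name)
            elif f.value_kind == "cigar_text" and value is not None:
                try:
                    parse_cigar(value)
                except CigarError as exc:
                    err("TYPE", f"{f.name}: unparseable CIGAR ({exc})", f.name)

    if config.enabled("INTERVAL"):
        for start_name, end_name in _interval_pairs(schema):
            start, end = get(start_name), get(end_name)
            if start is not None and end is not None and isinstance(start, int) \
                    and isinstance(end, int) and not (1 <= start <= end):
                err("INTERVAL", f"[{start_name}={start}, {end_name}={end}] violates "
                    "1 <= start <= end", start_name)

    junction = get("junction")
    if config.enabled("JUNC_LEN"):
        jlen = get("junction_length")
        if junction is not None and isinstance(jlen, int) and jlen != len(junction):
            err("JUNC_LEN", f"junction_length={jlen} but junction has {len(junction)} nt",
                "junction_length")

    if config.enabled("JUNC_AA"):
        jaa = get("junction_aa")
        if junction is not None and isinstance(jaa, str) \
                and 3 * len(jaa) != len(junction):
            err("JUNC_AA", f"3 x {len(jaa)} aa != {len(junction)} nt", "junction_aa")

    if config.enabled("CIGAR_SPAN"):
        for gene in GENES:
            cigar = get(f"{gene}_cigar")
            if not isinstance(cigar, str):
                continue
            try:
                ops = parse_cigar(cigar)
            except CigarError:
                continue  # TYPE already covers parse failures
            q_span, r_span = aligned_spans(ops)
            s, e = get(f"{gene}_sequence_start"), get(f"{gene}_sequence_end")
            if isinstance(s, int) and isinstance(e, int) and s <= e and q_span != e - s + 1:
                err("CIGAR_SPAN", f"{gene}_cigar aligned query span {q_span} != "
                    f"{gene}_sequence interval length {e - s + 1}", f"{gene}_cigar")
            s, e = get(f"{gene}_germline_start"), get(f"{gene}_germline_end")
            if isinstance(s, int) and isinstance(e, int) and s <= e and r_span != e - s + 1:
                err("CIGAR_SPAN", f"{gene}_cigar aligned reference span {r_span} != "
                    f"{gene}_germline interval length {e - s + 1}", f"{gene}_cigar")

    if config.enabled("REGION_BOUNDS"):
        sequence = get("sequence")
        if isinstance(sequence, str):
            n = len(sequence)
            for region in REGIONS:
                for name in (f"{region}_start", f"{region}_end"):
                    pos = get(name)
                    if isinstance(pos, int) and not (1 <= pos <= n):
                        err("REGION_BOUNDS",
                            f"{name}={pos} outside [1, {n}] of sequence", name)

    if config.enabled("ALN_LEN"):
        sa, ga = get("sequence_alignment"), get("germline_alignment")
        if isinstance(sa, str) and isinstance(ga, str) and len(sa) != len(ga):
            err("ALN_LEN", f"sequence_alignment ({len(sa)}) and germline_alignment "
                f"({len(ga)}) differ in length", "sequence_alignment")

    if config.enabled("IDENTITY_RANGE"):
        for gene in GENES:
            ident = get(f"{gene}_identity")
            if isinstance(ident, (int, float)) and not isinstance(ident, bool):
                if not (0 <= ident <= 100):
                    warn("IDENTITY_RANGE", f"{gene}_identity={ident} outside [0,1] and "
                         f"[0,100]", f"{gene}_identity")

    if config.enabled("ALPHABET"):
        for f in schema:
            value = get(f.name)
            if not isinstance(value, str):
                continue
            if f.value_kind == "nt_sequence":
                bad = set(value.upper()) - NT_ALPHABET
            elif f.value_kind == "gapped_nt_sequence":
                bad = set(value.upper()) - NT_ALPHABET - GAP_CHARS
            elif f.value_kind == "aa_sequence":
                bad = set(value.upper()) - AA_ALPHABET
            else:
                continue
            if bad:
                warn("ALPHABET", f"{f.name} contains unexpected characters "
                     f"{''.join(sorted(bad))!r}", f.name)

    if config.enabled("PRODUCTIVE_CONSISTENCY"):
        productive = get("productive")
        jaa = get("junction_aa")
        if productive is True and junction is not None:
            if len(junction) % 3 != 0:
                warn("PRODUCTIVE_CONSISTENCY",
                     "productive=T but junction is out of frame", "productive")
            elif isinstance(jaa, str) and "*" in jaa:
                warn("PRODUCTIVE_CONSISTENCY",
                     "productive=T but junction translation contains a stop", "productive")

    return issues


def validate_records(records: Iterable[RearrangementRecord],
                     schema: RearrangementSchema | None = None,
                     config: RuleConfig | None = None,
                     header_issues: Iterable[ValidationIssue] = (),
                     ) -> ValidationReport:
    """Stream records through :func:`validate_record`, aggregating a report."""
    if schema is None:
        schema = default_schema()
    report = ValidationReport()
    for issue in header_issues:
        report.add(issue)
    for i, rec in enumerate(records):
        report.total_records += 1
        for issue in validate_record(rec, schema, config, record_index=i):
            report.add(issue)
    return report


def validate_dataset(handle: DatasetHandle | str, schema: RearrangementSchema | None = None,
                     config: RuleConfig | None = None) -> ValidationReport:
    """Validate a whole dataset (handle or single path) without materializing it.

    Header rules run per member file; record rules run on the lazy
    concatenated stream.  Cells that fail type coercion on read (lenient
    mode nulls them) surface as TYPE errors; malformed rows surface as
    ROW_SHAPE errors.
    """
    from .tsv_io import concat_datasets, read_rearrangements

    if schema is None:
        schema = default_schema()
    if not isinstance(handle, DatasetHandle):
        handle = concat_datasets([handle], schema)
    report = ValidationReport()
    index = 0
    for path in handle.sources:
        file_report, records = read_rearrangements(path, schema, strictness="lenient")
        for issue in validate_header(file_report.columns, schema, config):
            report.add(issue)
        for rec in records:
            report.total_records += 1
            for issue in validate_record(rec, schema, config, record_index=index):
                report.add(issue)
            index += 1
        cfg = config or RuleConfig()
        for raw in file_report.issues:
            rule = raw["rule"] if raw["rule"] in ("TYPE", "ROW_SHAPE") else "ROW_SHAPE"
            if rule == "TYPE" and not cfg.enabled("TYPE"):
                continue
            report.add(ValidationIssue(rule, ERROR, raw["message"],
                                       record_index=raw.get("row"), field=raw.get("field")))
    return report
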