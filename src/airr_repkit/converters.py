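"""Mapping-driven conversion of legacy tabular dialects into the standard.

Legacy annotation tables (Change-O-like, IMGT-summary-like) differ from
the Rearrangement standard in field names, coordinate conventions
(length fields instead of end fields, occasionally 0-based starts),
boolean spellings, and alignment encoding (BLAST BTOP instead of
CIGAR).  A :class:`MappingProfile` captures those differences as a data
file — an ordered list of (source column, target field, transform)
entries plus dialect options — so a corrected correspondence table is a
config change, not a code change.

Conversion never invents values: every non-null target is produced from
exactly one source cell through one declared transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import yaml

from .alignment_utils import btop_to_cigar, cigar_to_string, end_from_length
from .errors import ConversionError, ProfileError
from .schema_model import RearrangementSchema, default_schema
from .tsv_io import (
    CoercionError,
    RearrangementRecord,
    coerce_value,
    render_value,
    write_rearrangements,
)
from .validation import RuleConfig, validate_record

TRANSFORMS = ("copy", "rename", "end_from_length", "length_from_end", "shift_base",
              "btop_to_cigar", "bool_norm", "drop")
#: transforms with an exact inverse, usable by :func:`export_legacy`
INVERTIBLE_TRANSFORMS = ("copy", "rename", "end_from_length", "length_from_end",
                         "shift_base", "bool_norm")

_DEFAULT_TRUE = ("T", "TRUE", "true")
_DEFAULT_FALSE = ("F", "FALSE", "false")


@dataclass(frozen=True)
class FieldMapping:
    """One source-column -> target-field rule."""

    source: str
    target: str | None
    transform: str = "copy"
    args: Mapping = dc_field(default_factory=dict)


@dataclass(frozen=True)
class MappingProfile:
    """A loadable conversion recipe: ordered mappings plus dialect options.

    ``base`` is the coordinate base of the *source* dialect (1 for
    SAM/IMGT-style closed coordinates, 0 for BED-style starts); starts
    are shifted to 1-based before any interval arithmetic.
    """

    name: str
    mappings: tuple[FieldMapping, ...]
    delimiter: str = "\t"
    null_tokens: tuple[str, ...] = ("",)
    base: int = 1
    custom_targets: tuple[str, ...] = ()

    def mapping_for_source(self, source: str) -> FieldMapping | None:
        for m in self.mappings:
            if m.source == source:
                return m
        return None


def load_profile(document: Mapping, schema: RearrangementSchema | None = None,
                 ) -> MappingProfile:
    """Validate and build a profile from a parsed YAML document.

    Rejects unknown transforms, duplicate targets, and targets that are
    neither schema fields nor declared custom targets.
    """
    if schema is None:
        schema = default_schema()
    if "name" not in document:
        raise ProfileError("profile document declares no name")
    dialect = document.get("dialect", {})
    custom_targets = tuple(document.get("custom_targets", ()))
    mappings: list[FieldMapping] = []
    seen_targets: set[str] = set()
    for entry in document.get("mappings", ()):
        transform = entry.get("transform", "copy")
        if transform not in TRANSFORMS:
            raise ProfileError(f"unknown transform {transform!r} for source "
                               f"{entry.get('source')!r}")
        target = entry.get("target")
        if transform == "drop":
            target = None
        elif target is None:
            raise ProfileError(f"mapping for source {entry.get('source')!r} has no target")
        else:
            if target in seen_targets:
                raise ProfileError(f"two mappings share target {target!r}")
            seen_targets.add(target)
            if target not in schema and target not in custom_targets:
                raise ProfileError(f"target {target!r} is neither a schema field nor a "
                                   "declared custom target")
        args = dict(entry.get("args", {}))
        if transform in ("end_from_length", "length_from_end") and "start_source" not in args:
            raise ProfileError(f"transform {transform!r} for source "
                               f"{entry.get('source')!r} requires args.start_source")
        mappings.append(FieldMapping(source=entry["source"], target=target,
                                     transform=transform, args=args))
    base = int(dialect.get("base", 1))
    if base not in (0, 1):
        raise ProfileError(f"unsupported coordinate base {base}")
    return MappingProfile(
        name=document["name"],
        mappings=tuple(mappings),
        delimiter=dialect.get("delimiter", "\t"),
        null_tokens=tuple(dialect.get("null_tokens", ("",))),
        base=base,
        custom_targets=custom_targets,
    )


def load_profile_file(source: str | Path | IO,
                      schema: RearrangementSchema | None = None) -> MappingProfile:
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    return load_profile(doc, schema)


def bundled_profile(name: str, schema: RearrangementSchema | None = None) -> MappingProfile:
    """Load a profile shipped with the package ('changeo-like', 'imgt-summary-like')."""
    ref = resources.files("airr_repkit").joinpath(f"data/profiles/{name.replace('-', '_')}.yaml")
    if not ref.is_file():
        raise ProfileError(f"no bundled profile named {name!r}")
    with ref.open("r", encoding="utf-8") as fh:
        return load_profile_file(fh, schema)


def _null(raw: str | None, profile: MappingProfile) -> str | None:
    if raw is None or raw in profile.null_tokens:
        return None
    return raw


def _source_start_1based(row: Mapping[str, str], mapping: FieldMapping,
                         profile: MappingProfile) -> int | None:
    start_raw = _null(row.get(mapping.args["start_source"]), profile)
    if start_raw is None:
        return None
    return int(start_raw) + (1 - profile.base)


def apply_transform(raw: str, mapping: FieldMapping, profile: MappingProfile,
                    row: Mapping[str, str]):
    """Transform one non-null source cell into a target cell string."""
    t = mapping.transform
    if t in ("copy", "rename"):
        return raw
    if t == "shift_base":
        offset = int(mapping.args.get("offset", 1 - profile.base))
        return str(int(raw) + offset)
    if t == "end_from_length":
        start = _source_start_1based(row, mapping, profile)
        if start is None:
            raise ValueError(f"start column {mapping.args['start_source']!r} is null; "
                             "cannot derive an end coordinate")
        end = end_from_length(start, int(raw))
        return "" if end is None else str(end)
    if t == "length_from_end":
        start = _source_start_1based(row, mapping, profile)
        if start is None:
            raise ValueError(f"start column {mapping.args['start_source']!r} is null; "
                             "cannot derive a length")
        end = int(raw) + (1 - profile.base)
        return str(end - start + 1)
    if t == "bool_norm":
        true_tokens = tuple(mapping.args.get("true_tokens", _DEFAULT_TRUE))
        false_tokens = tuple(mapping.args.get("false_tokens", _DEFAULT_FALSE))
        if raw in true_tokens:
            return "T"
        if raw in false_tokens:
            return "F"
        raise ValueError(f"cannot normalize {raw!r} as boolean")
    if t == "btop_to_cigar":
        mode = mapping.args.get("mode", "M")
        return cigar_to_string(btop_to_cigar(raw, mode))
    raise ValueError(f"transform {t!r} produces no target value")


def convert_record(source_row: Mapping[str, str], profile: MappingProfile,
                   schema: RearrangementSchema | None = None,
                   ) -> tuple[RearrangementRecord, list[str]]:
    """Convert one parsed legacy row; unmapped target fields stay null.

    Transform failures are collected as issue strings (the target stays
    null); they are not fatal here — strictness is a file-level policy.
    """
    if schema is None:
        schema = default_schema()
    values: dict = {name: None for name in schema.field_names}
    custom: dict = {name: None for name in profile.custom_targets}
    issues: list[str] = []
    for mapping in profile.mappings:
        if mapping.transform == "drop" or mapping.target is None:
            continue
        raw = _null(source_row.get(mapping.source), profile)
        if raw is None:
            continue
        try:
            cell = apply_transform(raw, mapping, profile, source_row)
            spec = schema.get(mapping.target)
            if spec is None:
                custom[mapping.target] = cell if cell != "" else None
            else:
                values[mapping.target] = coerce_value(cell, spec.value_kind,
                                                      field=mapping.target)
        except (ValueError, CoercionError, ConversionError) as exc:
            issues.append(f"{mapping.source} -> {mapping.target}: {exc}")
    return RearrangementRecord(values=values, custom=custom), issues


def convert_file(source_path: str | Path, profile: MappingProfile,
                 schema: RearrangementSchema | None = None,
                 sink: str | Path | None = None,
                 strict: bool = False) -> tuple[int, list[str]]:
    """Convert a whole legacy table; returns (converted count, issues).

    The output is a valid canonical-order Rearrangement TSV.  In strict
    mode any transform failure, or a converted record that fails
    record-level validation, aborts with the offending row index.
    """
    if schema is None:
        schema = default_schema()
    issues: list[str] = []
    records: list[RearrangementRecord] = []
    with open(source_path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ConversionError(f"{source_path}: empty source file")
        columns = header_line.rstrip("\r\n").split(profile.delimiter)
        if profile.mappings and not any(m.source in columns for m in profile.mappings):
            raise ConversionError(
                f"{source_path}: header shares no columns with the {profile.name!r} "
                f"dialect (delimiter {profile.delimiter!r} yields {columns[:3]!r})")
        missing_sources = sorted({m.source for m in profile.mappings
                                  if m.target is not None and m.source not in columns})
        if missing_sources:
            issues.append("absent source columns: " + ", ".join(missing_sources))
        config = RuleConfig()
        for row_index, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if line == "":
                continue
            cells = line.split(profile.delimiter)
            if len(cells) != len(columns):
                msg = f"row {row_index}: expected {len(columns)} cells, got {len(cells)}"
                if strict:
                    raise ConversionError(msg, row_index=row_index)
                issues.append(msg)
                continue
            row = dict(zip(columns, cells))
            record, row_issues = convert_record(row, profile, schema)
            if row_issues:
                if strict:
                    raise ConversionError(f"row {row_index}: {'; '.join(row_issues)}",
                                          row_index=row_index)
                issues.extend(f"row {row_index}: {msg}" for msg in row_issues)
            if strict:
                errors = [i for i in validate_record(record, schema, config)
                          if i.severity == "error"]
                if errors:
                    raise ConversionError(
                        f"row {row_index}: converted record fails validation: "
                        f"{errors[0].message}", row_index=row_index)
            records.append(record)
    if sink is not None:
        write_rearrangements(records, sink, schema)
    return len(records), issues


# ---------------------------------------------------------------------------
# inverse direction (legacy export) and helpers
# ---------------------------------------------------------------------------


def invertible_profile(profile: MappingProfile) -> MappingProfile:
    """The sub-profile of mappings with exact inverses (drops BTOP and drop)."""
    kept = tuple(m for m in profile.mappings
                 if m.target is not None and m.transform in INVERTIBLE_TRANSFORMS)
    return MappingProfile(name=profile.name + "-invertible", mappings=kept,
                          delimiter=profile.delimiter, null_tokens=profile.null_tokens,
                          base=profile.base, custom_targets=profile.custom_targets)


def _export_cell(record: RearrangementRecord, mapping: FieldMapping,
                 profile: MappingProfile, schema: RearrangementSchema) -> str:
    """Inverse of :func:`apply_transform` for one mapping."""
    t = mapping.transform
    null_token = profile.null_tokens[0]
    target = mapping.target
    assert target is not None
    value = record.get(target)
    if value is None:
        return null_token
    if t in ("copy", "rename"):
        spec = schema.get(target)
        return render_value(value, spec.value_kind, field=target) if spec else str(value)
    if t == "shift_base":
        offset = int(mapping.args.get("offset", 1 - profile.base))
        return str(int(value) - offset)
    if t == "end_from_length":
        # legacy column carries a length; recover it from the target end and
        # the start field that the start_source column maps to
        start_mapping = profile.mapping_for_source(mapping.args["start_source"])
        if start_mapping is None or start_mapping.target is None:
            raise ProfileError(f"cannot invert {mapping.source!r}: start source "
                               f"{mapping.args['start_source']!r} is not itself mapped")
        start = record.get(start_mapping.target)
        if start is None:
            return null_token
        # the record's start is already 1-based, as is the target end
        return str(int(value) - int(start) + 1)
    if t == "length_from_end":
        start_mapping = profile.mapping_for_source(mapping.args["start_source"])
        if start_mapping is None or start_mapping.target is None:
            raise ProfileError(f"cannot invert {mapping.source!r}")
        start = record.get(start_mapping.target)
        if start is None:
            return null_token
        end_1b = int(start) + int(value) - 1
        return str(end_1b - (1 - profile.base))
    if t == "bool_norm":
        true_tokens = tuple(mapping.args.get("true_tokens", _DEFAULT_TRUE))
        false_tokens = tuple(mapping.args.get("false_tokens", _DEFAULT_FALSE))
        return true_tokens[0] if value else false_tokens[0]
    raise ProfileError(f"transform {t!r} is not invertible; export through "
                       "invertible_profile(...)")


def export_legacy(records: Iterable[RearrangementRecord], profile: MappingProfile,
                  sink: str | Path | IO[str],
                  schema: RearrangementSchema | None = None) -> int:
    """Write records in the legacy dialect described by ``profile``.

    Only invertible transforms are supported; pass the profile through
    :func:`invertible_profile` first if it carries BTOP or drop
    mappings.  Column order is the mapping order; nulls render as the
    dialect's first null token.
    """
    if schema is None:
        schema = default_schema()
    exportable = [m for m in profile.mappings if m.target is not None]
    for m in exportable:
        if m.transform not in INVERTIBLE_TRANSFORMS:
            raise ProfileError(f"transform {m.transform!r} (source {m.source!r}) is not "
                               "invertible; use invertible_profile() first")

    def emit(out: IO[str]) -> int:
        out.write(profile.delimiter.join(m.source for m in exportable) + "\n")
        count = 0
        for record in records:
            cells = [_export_cell(record, m, profile, schema) for m in exportable]
            out.write(profile.delimiter.join(cells) + "\n")
            count += 1
        return count

    if hasattr(sink, "write"):
        return emit(sink)
    with open(sink, "w", encoding="utf-8", newline="\n") as out:
        return emit(out)


def join_on_key(paths: Sequence[str | Path], key: str,
                delimiter: str = "\t") -> list[dict[str, str]]:
    """Outer-join several legacy tables on a shared key column.

    Convenience for dialects that spread annotations across multiple
    files; later files win on duplicate column names.
    """
    joined: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for path in paths:
        with open(path, "r", encoding="utf-8") as fh:
            columns = fh.readline().rstrip("\r\n").split(delimiter)
            if key not in columns:
                raise ConversionError(f"{path}: no key column {key!r}")
            for line in fh:
                line = line.rstrip("\r\n")
                if not line:
                    continue
                row = dict(zip(columns, line.split(delimiter)))
                k = row[key]
                if k not in joined:
                    joined[k] = {}
                    order.append(k)
                joined[k].update(row)
    return [joined[k] for k in order]
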