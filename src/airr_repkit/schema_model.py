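"""The Rearrangement schema as data: field catalogue, types, versioning.

The column definitions live in a machine-readable YAML document bundled
with the package (``data/rearrangement_schema.yaml``), not in code, so a
corrected field set is a config change.  Field names are stable by
policy: obsolete fields are deprecated and replaced under new names
rather than renamed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import IO, Iterator, Mapping

import yaml

from .errors import SchemaError, VersionError

CATEGORIES = (
    "input",
    "primary_annotations",
    "alignment_annotations",
    "alignment_positions",
    "region_sequence",
    "region_positions",
    "junction_lengths",
)

VALUE_KINDS = (
    "text",
    "nt_sequence",
    "aa_sequence",
    "gapped_nt_sequence",
    "integer",
    "coordinate",
    "number",
    "boolean",
    "cigar_text",
)

#: name-suffix conventions that force a value kind
SUFFIX_KINDS = (
    ("_aa", "aa_sequence"),
    ("_start", "coordinate"),
    ("_end", "coordinate"),
    ("_cigar", "cigar_text"),
    ("_alignment", "gapped_nt_sequence"),
    ("_score", "number"),
    ("_identity", "number"),
    ("_support", "number"),
)

# length-style names would otherwise hit the "_aa" rule via "junction_aa_length";
# suffixes are only consulted when the name *ends* with them, so no clash.

_VERSION_RE = re.compile(r"^(\d+)\.(\d+)\.(\d+)$")


def parse_version(text: str) -> tuple[int, int, int]:
    """Parse an ``X.Y.Z`` version string into an integer triple."""
    m = _VERSION_RE.match(str(text).strip())
    if not m:
        raise VersionError(f"malformed version {text!r}; expected X.Y.Z")
    return int(m.group(1)), int(m.group(2)), int(m.group(3))


def classify_version_change(old: tuple[int, int, int],
                            new: tuple[int, int, int]) -> str:
    """Highest-order differing component: 'major', 'minor', 'patch' or 'none'.

    Major-number changes are reserved for revisions touching multiple
    standards at once; minor tracks schema/API changes; patch tracks
    software/documentation-only updates.
    """
    for name, a, b in zip(("major", "minor", "patch"), old, new):
        if a != b:
            return name
    return "none"


def suffix_kind(name: str) -> str | None:
    """Value kind forced by the field-name suffix, if any."""
    for suffix, kind in SUFFIX_KINDS:
        if name.endswith(suffix):
            return kind
    return None


@dataclass(frozen=True)
class FieldSpec:
    """One column definition: name, category, value kind, requiredness.

    Every field — required or not — is nullable; null is encoded on disk
    as the empty string.  "Required" only means the column must be
    present in the TSV header.
    """

    name: str
    category: str
    value_kind: str
    required: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name or "\t" in self.name or "\n" in self.name or "\r" in self.name:
            raise SchemaError(f"invalid field name {self.name!r}")
        if self.category not in CATEGORIES:
            raise SchemaError(f"unknown category {self.category!r} for field {self.name!r}")
        if self.value_kind not in VALUE_KINDS:
            raise SchemaError(f"unknown value kind {self.value_kind!r} for field {self.name!r}")
        forced = suffix_kind(self.name)
        if forced is not None and self.value_kind != forced:
            raise SchemaError(
                f"field {self.name!r} must have value kind {forced!r} by suffix rule, "
                f"got {self.value_kind!r}")


@dataclass(frozen=True)
class RearrangementSchema:
    """A versioned, ordered catalogue of :class:`FieldSpec` definitions."""

    version: tuple[int, int, int]
    fields: tuple[FieldSpec, ...]
    _by_name: Mapping[str, FieldSpec] = dc_field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        by_name = {}
        for f in self.fields:
            if f.name in by_name:
                raise SchemaError(f"duplicate field name {f.name!r}")
            by_name[f.name] = f
        object.__setattr__(self, "_by_name", by_name)

    def __iter__(self) -> Iterator[FieldSpec]:
        return iter(self.fields)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> FieldSpec:
        return self._by_name[name]

    def get(self, name: str) -> FieldSpec | None:
        return self._by_name.get(name)

    @property
    def field_names(self) -> tuple[str, ...]:
        """Canonical column order (the schema-document order)."""
        return tuple(f.name for f in self.fields)

    @property
    def required_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.fields if f.required)

    @property
    def version_string(self) -> str:
        return ".".join(map(str, self.version))


def is_custom_field(schema: RearrangementSchema, name: str) -> bool:
    """True iff ``name`` is not a declared schema field.

    Custom columns are legal anywhere as long as their names are unique;
    they are carried through I/O untyped (as text).  Note the comparison
    is exact: a declared name with stray whitespace is "custom" here and
    flagged by header validation instead.
    """
    if not name:
        raise ValueError("empty field name")
    return name not in schema


def _check_interval_pairs(schema: RearrangementSchema) -> None:
    for f in schema:
        if f.name.endswith("_start"):
            partner = f.name[: -len("_start")] + "_end"
            p = schema.get(partner)
            if p is None or p.category != f.category:
                raise SchemaError(
                    f"field {f.name!r} has no {partner!r} partner in category {f.category!r}")
        elif f.name.endswith("_end"):
            partner = f.name[: -len("_end")] + "_start"
            p = schema.get(partner)
            if p is None or p.category != f.category:
                raise SchemaError(
                    f"field {f.name!r} has no {partner!r} partner in category {f.category!r}")


def load_schema(document: Mapping, *, check_interval_pairs: bool = True) -> RearrangementSchema:
    """Build a :class:`RearrangementSchema` from a parsed schema document.

    The document declares ``version: "X.Y.Z"`` and a ``fields`` list; each
    entry gives ``name``, ``category``, optionally ``value_kind`` (derived
    from the name suffix when omitted; defaults to ``text``), ``required``
    and ``description``.  Duplicate names are rejected.  Unless disabled,
    every ``*_start`` field must have a ``*_end`` partner in the same
    category and vice versa.
    """
    if "version" not in document:
        raise VersionError("schema document declares no version")
    version = parse_version(document["version"])
    raw_fields = document.get("fields")
    if not raw_fields:
        raise SchemaError("schema document declares no fields")
    specs = []
    for entry in raw_fields:
        name = entry.get("name")
        if name is None:
            raise SchemaError(f"field entry without a name: {entry!r}")
        kind = entry.get("value_kind") or suffix_kind(name) or "text"
        specs.append(FieldSpec(
            name=name,
            category=entry.get("category", "primary_annotations"),
            value_kind=kind,
            required=bool(entry.get("required", False)),
            description=entry.get("description", ""),
        ))
    schema = RearrangementSchema(version=version, fields=tuple(specs))
    if check_interval_pairs:
        _check_interval_pairs(schema)
    return schema


def serialize_schema(schema: RearrangementSchema) -> dict:
    """Inverse of :func:`load_schema`: load(serialize(s)) == s."""
    return {
        "version": schema.version_string,
        "fields": [
            {
                "name": f.name,
                "category": f.category,
                "value_kind": f.value_kind,
                "required": f.required,
                "description": f.description,
            }
            for f in schema
        ],
    }


def load_schema_file(source: str | IO) -> RearrangementSchema:
    """Load a schema from a YAML document (path or open stream)."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise SchemaError("schema document is not a mapping")
    return load_schema(doc)


_DEFAULT_SCHEMA: RearrangementSchema | None = None


def default_schema() -> RearrangementSchema:
    """The bundled Rearrangement schema (standard v1.2.0), cached."""
    global _DEFAULT_SCHEMA
    if _DEFAULT_SCHEMA is None:
        ref = resources.files("airr_repkit").joinpath("data/rearrangement_schema.yaml")
        with ref.open("r", encoding="utf-8") as fh:
            _DEFAULT_SCHEMA = load_schema_file(fh)
    return _DEFAULT_SCHEMA
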