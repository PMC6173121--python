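"""Exception hierarchy for the toolkit.

Every error raised on purpose by this package derives from
:class:`AirrRepkitError`, so callers (and the CLI) can distinguish
"your data/config is bad" from genuine bugs.
"""


class AirrRepkitError(Exception):
    """Base class for all package errors."""


class SchemaError(AirrRepkitError):
    """Malformed schema document (duplicate fields, bad categories, ...)."""


class VersionError(SchemaError):
    """Version string does not parse as X.Y.Z."""


class CoercionError(AirrRepkitError):
    """A non-empty cell could not be parsed as its declared value kind."""

    def __init__(self, message: str, *, kind: str | None = None, text: str | None = None,
                 field: str | None = None):
        super().__init__(message)
        self.kind = kind
        self.text = text
        self.field = field


class HeaderError(AirrRepkitError):
    """Unusable TSV header (duplicate column names, missing required in strict mode)."""


class RowError(AirrRepkitError):
    """A data row that cannot be interpreted (wrong cell count, bad value in strict mode)."""

    def __init__(self, message: str, *, row_index: int | None = None):
        super().__init__(message)
        self.row_index = row_index


class RenderError(AirrRepkitError):
    """A typed value cannot be serialized to a TSV cell."""


class CompatibilityError(AirrRepkitError):
    """Dataset members do not share the required-column set."""


class UnsupportedOperationError(AirrRepkitError):
    """Operation impossible for this source, e.g. split reads on plain gzip."""


class CigarError(AirrRepkitError):
    """Malformed CIGAR text or inconsistent alignment geometry."""

    def __init__(self, message: str, *, position: int | None = None):
        super().__init__(message)
        self.position = position


class BtopError(AirrRepkitError):
    """Malformed BLAST traceback (BTOP) text."""

    def __init__(self, message: str, *, position: int | None = None):
        super().__init__(message)
        self.position = position


class ProfileError(AirrRepkitError):
    """Malformed field-mapping profile document."""


class ConversionError(AirrRepkitError):
    """Fatal conversion failure (strict mode, or unusable source dialect)."""

    def __init__(self, message: str, *, row_index: int | None = None):
        super().__init__(message)
        self.row_index = row_index


class SimulationError(AirrRepkitError):
    """Impossible recombination geometry after bounded retries."""
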