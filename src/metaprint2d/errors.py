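"""Exception hierarchy for metaprint2d."""


class MetaPrintError(Exception):
    """Base class for all metaprint2d errors."""


class ParseError(MetaPrintError):
    """A structure or reaction record could not be parsed."""

    def __init__(self, message: str, record: str | int | None = None):
        self.record = record
        super().__init__(message if record is None else f"{message} (record {record})")


class TypingError(MetaPrintError):
    """An atom could not be assigned a Sybyl type."""

    def __init__(self, message: str, atom_index: int | None = None):
        self.atom_index = atom_index
        super().__init__(message)


class TypeLookupError(MetaPrintError, KeyError):
    """Unknown Sybyl type name or index."""


class MappingError(MetaPrintError):
    """Atom-map numbers on a transformation record are missing or invalid."""

    def __init__(self, message: str, record_id: str | None = None):
        self.record_id = record_id
        super().__init__(message if record_id is None else f"{message} (record_id={record_id})")


class ContractViolationError(MetaPrintError):
    """A caller violated an operation precondition (e.g. depth mismatch)."""


class IncompatibilityError(MetaPrintError):
    """Database and query disagree on depth or type table."""


class CorruptionError(MetaPrintError):
    """A serialised database failed a consistency check."""

    def __init__(self, message: str, offset: int | None = None, record_index: int | None = None):
        self.offset = offset
        self.record_index = record_index
        super().__init__(message)


class TruncationError(CorruptionError):
    """A serialised database ended before its declared content."""


class FixtureError(MetaPrintError):
    """The synthetic-corpus generator could not satisfy its spec."""
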