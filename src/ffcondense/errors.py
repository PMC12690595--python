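"""Exception hierarchy shared across the package."""


class FFCondenseError(Exception):
    """Base class for all package errors."""


class ParseError(FFCondenseError):
    """A structure file record could not be parsed; names the offending line."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class StructureError(FFCondenseError):
    """Topology-level inconsistency (bad indices, duplicate bonds, disconnected graph)."""


class DegenerateGeometryError(FFCondenseError):
    """An internal coordinate is undefined at the given Cartesian geometry."""


class ConfigurationError(FFCondenseError):
    """Invalid pattern, option or engine configuration."""


class SchemaError(FFCondenseError):
    """A parameter record violates the record schema (arity, category, value)."""


class UnitError(FFCondenseError):
    """Unknown unit tag, or clashing units within one parameter name."""


class ConsistencyError(FFCondenseError):
    """An enumerated interaction is neither parametrized nor recorded as dropped."""


class AssignmentError(FFCondenseError):
    """Parameter assignment cannot proceed (untyped atoms, empty table)."""


class ModelError(FFCondenseError):
    """A model precondition is violated (e.g. non-positive hardness)."""


class FormatError(FFCondenseError):
    """A serialized table or parameter file is malformed or version-incompatible."""
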