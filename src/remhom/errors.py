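"""Exception hierarchy shared across the package."""


class RemhomError(Exception):
    """Base class for all package-specific errors."""


class SccsParseError(RemhomError, ValueError):
    """A SCOP concise classification string could not be parsed."""


class SchemaError(RemhomError, ValueError):
    """An input file violates the expected schema or format."""


class DuplicateIdError(RemhomError, ValueError):
    """Two records in one database share a domain identifier."""


class ParameterError(RemhomError, ValueError):
    """A user-supplied parameter is outside its valid range."""


class ClassificationDepthError(RemhomError, ValueError):
    """A classification path is too shallow for the requested operation."""


class DimensionMismatchError(RemhomError, ValueError):
    """Vectors in one representation store do not share a dimension."""


class MissingRepresentationError(RemhomError, KeyError):
    """A domain referenced by a task has no stored representation."""


class MissingScoreError(RemhomError, KeyError):
    """A (query, candidate) pair has no entry in a supplied score matrix."""


class DegenerateRepresentationError(RemhomError, ValueError):
    """A representation has zero norm and cannot enter cosine similarity."""


class UndefinedMetricError(RemhomError, ValueError):
    """A ranking metric is undefined for the given label configuration."""
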