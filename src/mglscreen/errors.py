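"""Exception hierarchy for the screening pipeline.

Every error raised on purpose by this package derives from
:class:`MglError`, so callers (and the CLI) can distinguish expected
failure modes from bugs.
"""


class MglError(Exception):
    """Base class for all package errors."""


class EmptyInputError(MglError):
    """An input that must be non-empty was empty."""


class DuplicateIdError(MglError):
    """Two records in one collection share an identifier."""


class FastaParseError(MglError):
    """Malformed FASTA text; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class FormatError(MglError):
    """A file is not in the expected format (wrong magic, wrong dialect)."""


class AlignmentShapeError(MglError):
    """Rows of an alignment have unequal lengths."""


class SchemaError(MglError):
    """A table is missing required columns or has malformed rows."""


class DegenerateModelError(MglError):
    """A profile HMM could not be built (e.g. zero match columns)."""


class AlphabetError(MglError):
    """A residue is outside the alphabet a scoring matrix supports."""


class AnchorInconsistencyError(MglError):
    """A reference sequence does not carry its declared anchor motifs."""


class MissingTaxonomyError(MglError):
    """Verdict ids absent from the taxonomy table."""

    def __init__(self, missing_ids):
        self.missing_ids = list(missing_ids)
        super().__init__(
            "ids missing from taxonomy table: " + ", ".join(self.missing_ids)
        )


class LineageError(MglError):
    """A lineage string does not have the expected seven ranks."""


class MappingError(MglError):
    """A record id is absent from a record-to-genome mapping."""


class SaturationError(MglError):
    """Poisson distance undefined: observed p-distance >= 1."""


class OverlapError(MglError):
    """Two aligned rows share no ungapped columns."""


class TreeError(MglError):
    """Invalid distance matrix or malformed Newick text."""


class InsufficientDataError(MglError):
    """Too few points to fit a standard curve."""


class DegenerateDesignError(MglError):
    """All standard-curve concentrations identical; slope undefined."""


class UnusableCurveError(MglError):
    """A standard curve with zero slope cannot be inverted."""


class AmbiguityError(MglError):
    """Sequence contains residues whose mass is undefined (X etc.)."""


class ConfigError(MglError):
    """Invalid pipeline configuration (missing files, bad values)."""
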