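"""Exception hierarchy shared across the package."""


class OrthoforgeError(Exception):
    """Base class for all package-specific errors."""


class FullTableParseError(OrthoforgeError):
    """A BUSCO full-table file could not be parsed; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class AlignmentError(OrthoforgeError):
    """An aligner backend failed or produced unusable output."""


class PhylipFormatError(OrthoforgeError):
    """A relaxed-phylip file is malformed."""


class PartitionError(OrthoforgeError):
    """A partition scheme violates contiguity/coverage invariants."""


class OccupancyError(OrthoforgeError):
    """Occupancy construction or table parsing failed."""


class AnnotationError(OrthoforgeError):
    """A GO mapping table is malformed."""


class FetchError(OrthoforgeError):
    """Remote sequence retrieval failed."""


class FixtureError(OrthoforgeError):
    """A synthetic-fixture specification is invalid."""
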