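"""Exception hierarchy for karyoevo."""


class KaryoevoError(Exception):
    """Base class for all karyoevo errors."""


class InvalidMeasurementError(KaryoevoError):
    """Arm lengths are negative or not oriented with p <= q."""


class IncompleteKaryotypeError(KaryoevoError):
    """A karyotype lacks a field (morphology, rel_length, ...) an operation needs."""


class DegenerateInputError(KaryoevoError):
    """Input is structurally valid but degenerate (zero-length complement, all-missing character, ...)."""


class CodingError(KaryoevoError):
    """A raw cytogenetic observation cannot be coded into a character state."""


class MatrixFormatError(KaryoevoError):
    """A character matrix cannot be serialized in the requested format."""


class MatrixParseError(KaryoevoError):
    """A character-matrix file is malformed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NewickParseError(KaryoevoError):
    """A Newick string is malformed (unbalanced parentheses, duplicate leaves, ...)."""


class CharacterNotFoundError(KaryoevoError, LookupError):
    """The requested character is absent from the matrix."""


class InstanceTooLargeError(KaryoevoError):
    """The brute-force oracle was asked for an instance beyond exhaustive enumeration."""


class ConfigError(KaryoevoError):
    """Invalid run configuration or filter key."""
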