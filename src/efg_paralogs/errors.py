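"""Exception hierarchy shared across the pipeline."""


class EfgError(Exception):
    """Base class for all pipeline errors."""


class AlignmentError(EfgError):
    """Sequences of unequal length, or an otherwise invalid alignment."""


class FormatError(EfgError):
    """Malformed input file (duplicate ids, illegal characters, empty file)."""


class SpecError(EfgError):
    """Unsatisfiable synthetic-data request."""


class PatternParseError(EfgError):
    """Illegal character in a motif pattern string."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class ConsistencyError(EfgError):
    """Inputs that contradict each other (mismatched positions, presence vs deletions)."""


class SequenceError(EfgError):
    """Coding sequences that violate frame or length preconditions."""


class ConfigError(EfgError):
    """Missing or invalid configuration (empty pattern lists, marker sets...)."""
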