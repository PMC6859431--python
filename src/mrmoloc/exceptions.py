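"""Exception hierarchy for mrmoloc."""


class MrmolocError(Exception):
    """Base class for all package errors."""


class FormatError(MrmolocError):
    """A file does not conform to the expected tabular format."""


class ValidationError(MrmolocError):
    """A record violates a field-level invariant (bounds, signs, consistency)."""


class ParameterError(MrmolocError):
    """A function argument is outside its admissible range."""


class AnalysisError(MrmolocError):
    """An analysis cannot proceed (no shared instruments, too few pairs, ...)."""


class SimulationError(MrmolocError):
    """A simulation produced degenerate data (e.g. zero cases for a binary trait)."""
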