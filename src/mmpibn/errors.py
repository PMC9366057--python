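"""Exception hierarchy for the package."""


class MmpiBnError(Exception):
    """Base class for all package errors."""


class StructuralError(MmpiBnError):
    """Invalid graph structure (cycle, self-loop, undeclared endpoint)."""


class FittingError(MmpiBnError):
    """Parameter fitting failed (singular design, empty data)."""


class DegenerateDensityError(MmpiBnError):
    """Density evaluation hit a zero-variance node at its deterministic value."""


class InsufficientDataError(MmpiBnError):
    """Too few rows for the requested statistical test."""


class MatchingError(MmpiBnError):
    """Propensity matching failed (separation, empty class)."""


class ModelFormatError(MmpiBnError):
    """Model file unreadable or of an unsupported version."""
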