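"""Exception hierarchy for the cubefret pipeline."""


class CubefretError(Exception):
    """Base class for all package errors."""


class ValidationError(CubefretError):
    """Input violates a documented container invariant."""


class FormatError(CubefretError):
    """A file could not be parsed as the documented format."""


class LayoutError(FormatError):
    """Channel layout of a stack file does not match the declaration."""


class ParameterError(CubefretError):
    """A processing parameter is outside its documented domain."""


class EstimationError(CubefretError):
    """Too little usable signal to estimate a quantity."""


class CoverageError(CubefretError):
    """A timestamp falls outside the condition protocol."""


class NormalizationError(CubefretError):
    """Baseline window empty or degenerate during normalization."""


class WindowError(CubefretError):
    """A requested condition window cannot be resolved."""


class StatisticsError(CubefretError):
    """Group too small or malformed for the requested statistic."""


class FitError(CubefretError):
    """Nonlinear fit failed to converge."""


class AlignmentError(CubefretError):
    """Two series share no overlapping time support."""


class PlacementError(CubefretError):
    """Synthetic cells could not be placed without overlap."""


class ConfigurationError(CubefretError):
    """Required configuration entry missing or inconsistent."""
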