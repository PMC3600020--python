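"""Exception hierarchy shared across the pipeline stages."""


class SpgaitError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SpgaitError, ValueError):
    """A parameter violates its domain (sign, positivity, finiteness)."""


class InvalidValueError(SpgaitError, ValueError):
    """A data value violates its domain (non-finite input, bad shape)."""


class SimulationDivergedError(SpgaitError, RuntimeError):
    """The ODE integrator failed (step underflow or non-finite state)."""

    def __init__(self, t_reached: float, message: str | None = None):
        self.t_reached = float(t_reached)
        super().__init__(
            message or f"oscillator simulation diverged at t = {t_reached:.6g} s"
        )


class InsufficientDataError(SpgaitError, ValueError):
    """A series is too short for the requested operation."""


class AlignmentError(SpgaitError, ValueError):
    """Channels share no overlapping time interval."""


class InsufficientStridesError(SpgaitError, ValueError):
    """Fewer than the required number of strides were detected."""


class InvalidStrideError(SpgaitError, ValueError):
    """A stride is degenerate (zero or negative duration)."""


class FitFailedError(SpgaitError, RuntimeError):
    """Every optimizer restart diverged."""

    def __init__(self, diagnostics, message: str | None = None):
        self.diagnostics = diagnostics
        super().__init__(message or f"all {len(diagnostics)} restart(s) failed")


class UndefinedCorrelationError(SpgaitError, ValueError):
    """Pearson correlation undefined (zero-variance channel)."""


class UndefinedStatisticError(SpgaitError, ValueError):
    """A test statistic is undefined for the given samples."""


class UndefinedNormalizationError(SpgaitError, ValueError):
    """Normalization impossible (all-zero reference values)."""


class ConfigError(SpgaitError, ValueError):
    """A configuration file is unreadable or contains unknown keys."""


class ParseError(SpgaitError, ValueError):
    """A data file violates its schema."""


class PipelineError(SpgaitError, RuntimeError):
    """The pipeline produced zero usable trials."""
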