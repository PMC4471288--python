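"""Exception hierarchy for ssridose."""


class SSRIDoseError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SSRIDoseError, ValueError):
    """Invalid parameter, schedule or profile."""


class DegenerateKineticsError(ValidationError):
    """Absorption and elimination rate constants coincide (flip-flop
    degenerate case); the bi-exponential solution is undefined."""


class HorizonError(SSRIDoseError):
    """The simulated horizon does not cover the requested quantity
    (e.g. the profile never falls far enough below its peak to measure
    a terminal half-life, or a daily window lies outside the grid)."""


class CalibrationError(SSRIDoseError):
    """Parameter calibration failed to reproduce the target observables."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class ConvergenceError(SSRIDoseError):
    """Iteration failed to converge; carries the last value reached."""

    def __init__(self, message, last_value=None):
        super().__init__(message)
        self.last_value = last_value


class InfeasibleDoseError(SSRIDoseError):
    """No dose within bounds achieves the daily target concentration."""

    def __init__(self, message, day=None):
        super().__init__(message)
        self.day = day


class InsufficientDataError(SSRIDoseError):
    """Too few records for the requested statistic."""


class UndefinedCorrelationError(SSRIDoseError):
    """Correlation undefined (zero variance in one of the variables)."""
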