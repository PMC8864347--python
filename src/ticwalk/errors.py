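"""Exception hierarchy for the ticwalk package."""


class TicWalkError(Exception):
    """Base class for all package-specific errors."""


class SessionFormatError(TicWalkError):
    """A sessions file is structurally malformed (e.g. a required column is missing)."""


class SessionValidationError(TicWalkError):
    """Session content violates an invariant (e.g. an event time outside the window)."""


class CalibrationError(TicWalkError):
    """The slope-to-dimension convention could not be anchored.

    Raised when no affine map places the ballistic walk at D_f = 2 and the
    Brownian ensemble mean at D_f = 1 within tolerance, for any admissible
    fit window. Carries both fitted slopes for diagnosis.
    """

    def __init__(self, message: str, ballistic_slope: float | None = None,
                 brownian_slope: float | None = None):
        super().__init__(message)
        self.ballistic_slope = ballistic_slope
        self.brownian_slope = brownian_slope


class InsufficientDataError(TicWalkError):
    """Too few sessions/subjects for the requested group statistic."""
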