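"""Exception hierarchy."""


class FilotrackError(Exception):
    """Base class for all package errors."""


class ParameterError(FilotrackError, ValueError):
    """Invalid parameter value or unknown registry name."""


class NoObjectError(FilotrackError):
    """A binary mask contains no foreground object."""


class OverErosionError(FilotrackError):
    """Erosion annihilated the mask; a smaller erode/dilate count is needed."""


class EditError(FilotrackError):
    """A track edit references a missing track/frame or cannot be applied."""


class SpecError(FilotrackError, ValueError):
    """A synthetic-movie specification is internally inconsistent."""


class DegenerateSeriesError(FilotrackError):
    """A time series is too short, constant, or otherwise unusable."""


class InvalidTransitionMatrixError(DegenerateSeriesError):
    """A fitted Markov transition matrix has an observed state with no
    outgoing transitions (or fewer than two states); the track is discarded."""


class RandomizationError(FilotrackError):
    """Block-randomization acceptance rate collapsed; carries diagnostics."""

    def __init__(self, message: str, n_attempts: int = 0, n_accepted: int = 0):
        super().__init__(message)
        self.n_attempts = n_attempts
        self.n_accepted = n_accepted
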