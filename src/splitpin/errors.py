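"""Exception hierarchy for the splitpin package.

Every error raised by the library derives from :class:`SplitPinError`
so the CLI can map domain failures onto distinct exit codes.
"""


class SplitPinError(Exception):
    """Base class for all splitpin domain errors."""

    exit_code = 1


class InvalidInputError(SplitPinError):
    """Input data violates a precondition (shape, sign, finiteness)."""

    exit_code = 2


class InvalidParametersError(SplitPinError):
    """Parameter values violate their constraints (e.g. m_in >= m_out)."""

    exit_code = 3


class NoSignalError(SplitPinError):
    """No pixel survives validity + intensity thresholding."""

    exit_code = 4


class DegenerateModulationError(SplitPinError):
    """The modulation histogram has no contrast; endpoints must be set manually."""

    exit_code = 5


class FitFailureError(SplitPinError):
    """The noise-free Gaussian fit did not converge."""

    exit_code = 6

    def __init__(self, message: str, delta_max: int | None = None):
        super().__init__(message)
        self.delta_max = delta_max


class PlacementError(SplitPinError):
    """Could not place the requested beads without overlap."""

    exit_code = 7


class StackFormatError(InvalidInputError):
    """A TIFF stack does not satisfy the stack conventions."""

    exit_code = 8


class TooFewFramesError(StackFormatError):
    exit_code = 9


class InconsistentStackError(StackFormatError):
    exit_code = 10


class UnsupportedFormatError(StackFormatError):
    exit_code = 11
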