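"""Exception hierarchy with dedicated exit codes for the command-line tool."""


class CoevoError(Exception):
    """Base class for all package errors. ``exit_code`` drives the CLI."""

    exit_code = 1


class MsaFormatError(CoevoError):
    """Malformed alignment input (ragged rows, bad records)."""


class EmptyInputError(MsaFormatError):
    """Alignment stream contained no sequences."""


class InsufficientWeightError(CoevoError):
    """Total effective alignment weight (Meff) below the required minimum."""

    exit_code = 2

    def __init__(self, meff: float, min_meff: float):
        self.meff = meff
        self.min_meff = min_meff
        super().__init__(
            f"insufficient total alignment weight: Meff={meff:g} < required {min_meff:g}"
        )


class IcmeTimeoutError(CoevoError):
    """Inverse covariance matrix estimation exceeded its time limit."""

    exit_code = 3


class DegenerateInputError(CoevoError):
    """Numerically degenerate input (e.g. non-positive mean diagonal)."""


class SingularMatrixError(CoevoError):
    """Covariance matrix could not be factorized; shrink or add pseudocounts."""


class NoColumnsRemainError(CoevoError):
    """Gap filtering removed every alignment column."""
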