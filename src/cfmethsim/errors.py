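"""Exception hierarchy for cfmethsim."""


class CfMethSimError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CfMethSimError, ValueError):
    """An object or file violates a structural invariant."""


class ParseError(ValidationError):
    """A text input could not be parsed; the message names the offending line."""


class DeconvolutionError(CfMethSimError, RuntimeError):
    """The constrained least-squares solver failed; carries the solver status."""

    def __init__(self, message: str, status: object = None):
        super().__init__(message)
        self.status = status


class DegenerateDataError(CfMethSimError, ValueError):
    """Input data are degenerate for the requested statistic (e.g. zero variance,
    zero informative calls)."""
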