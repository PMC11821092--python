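"""Exception hierarchy used across the package."""


class ChaosRefineError(Exception):
    """Base class for package-specific errors."""


class NumericalBlowupError(ChaosRefineError):
    """The integrator produced a non-finite state.

    Parameters
    ----------
    step : int
        Index of the integration step at which the state first became
        non-finite.
    """

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite state at integration step {step}")


class RefinementError(ChaosRefineError):
    """A refinement step could not produce a valid result.

    Parameters
    ----------
    step : str
        Name of the pipeline step that failed (e.g. ``"select_subclusters"``).
    """

    def __init__(self, step: str, message: str):
        self.step = step
        super().__init__(f"[{step}] {message}")


class SignalParseError(ChaosRefineError):
    """A signal file could not be parsed.

    Parameters
    ----------
    line : int or None
        1-based line number of the offending line, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
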