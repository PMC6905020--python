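"""Exception hierarchy for ionseg."""


class IonsegError(Exception):
    """Base class for all ionseg errors."""


class FormatError(IonsegError):
    """An input file violates its documented format."""


class ParameterError(IonsegError):
    """A parameter is outside its valid domain (e.g. even window length)."""


class TrackError(IonsegError):
    """A secondary-structure or solvent-accessibility track is missing or inconsistent."""


class ConvergenceError(IonsegError):
    """The SMO solver exceeded its iteration budget.

    Carries ``iterations`` and ``n_changed`` diagnostics.
    """

    def __init__(self, message: str, iterations: int = 0, n_changed: int = 0):
        super().__init__(message)
        self.iterations = iterations
        self.n_changed = n_changed
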