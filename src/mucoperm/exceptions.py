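"""Exception hierarchy for mucoperm."""


class MucopermError(Exception):
    """Base class for all mucoperm errors."""


class InvalidParameterError(MucopermError, ValueError):
    """A physical parameter is out of its admissible range."""


class InvalidStateError(MucopermError, ValueError):
    """A system state violates its invariants (e.g. negative mass)."""


class IntegrationError(MucopermError, RuntimeError):
    """The fixed-step integrator produced a non-finite or unphysical state.

    Carries the offending step index and time in ``step`` and ``time``.
    """

    def __init__(self, message: str, step: int | None = None,
                 time: float | None = None):
        super().__init__(message)
        self.step = step
        self.time = time


class InsufficientDataError(MucopermError, ValueError):
    """Too few usable data points for a regression."""


class ConfigError(MucopermError, ValueError):
    """A configuration file is malformed, incomplete, or has unknown keys."""
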