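"""Exception hierarchy shared across the package."""


class GlycothermError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GlycothermError):
    """A model/scenario definition is internally inconsistent or references
    unknown entities (species ids, reaction ids, file schema keys)."""


class DomainError(GlycothermError):
    """An input is outside the mathematical domain of an operation
    (negative concentration, temperature below T_min, nonpositive Keq)."""


class SteadyStateError(GlycothermError):
    """No steady state could be found; carries the last residual seen."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class SimulationError(GlycothermError):
    """Time integration failed; carries the last successfully reached time."""

    def __init__(self, message, last_time=None):
        super().__init__(message)
        self.last_time = last_time
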