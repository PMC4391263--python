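"""Exception hierarchy for the kinetics toolkit."""


class KineticsError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(KineticsError, ValueError):
    """A rate constant, concentration, or design value violates its domain."""


class SchemeError(KineticsError, ValueError):
    """A mechanism definition is internally inconsistent."""


class SimulationError(KineticsError, RuntimeError):
    """The ODE integrator failed; the message names the scheme and parameters."""


class FitError(KineticsError, RuntimeError):
    """A fit could not be carried out at all (as opposed to not converging)."""


class DegenerateFitError(FitError):
    """The data carry no information about the requested parameters."""


class ConfigError(KineticsError, ValueError):
    """A run configuration file is malformed or references missing inputs."""
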