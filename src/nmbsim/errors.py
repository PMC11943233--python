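"""Exception hierarchy.

The CLI maps these onto process exit codes: ConfigError -> 2,
ParseError -> 3, SimulationError -> 4.
"""


class NMBSimError(Exception):
    """Base class for all package errors."""


class InputError(NMBSimError, ValueError):
    """Invalid value passed to a computational routine."""


class ConfigError(NMBSimError, ValueError):
    """Invalid or unsatisfiable configuration."""


class ParseError(NMBSimError, ValueError):
    """Malformed external file (dosing record, parameter file)."""


class SimulationError(NMBSimError, RuntimeError):
    """Numerical failure inside the ODE engine."""


class ProtocolFailureError(NMBSimError, RuntimeError):
    """A dosing-protocol contract could not be met (e.g. no recovery)."""


class AnalysisError(NMBSimError, ValueError):
    """Endpoint extraction failed (e.g. recovery never observed)."""
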