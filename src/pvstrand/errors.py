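"""Exception hierarchy of the strand simulator."""


class PvstrandError(Exception):
    """Base class for all package errors."""


class ParameterError(PvstrandError, ValueError):
    """An argument is outside its admissible range."""


class InvalidStateError(PvstrandError, ValueError):
    """A membrane state component is non-finite or out of bounds."""


class ConfigurationError(PvstrandError, ValueError):
    """A tissue/protocol configuration violates its invariants."""


class StabilityError(PvstrandError, RuntimeError):
    """An explicit step exceeds its stability bound."""


class DivergenceError(PvstrandError, RuntimeError):
    """The integrator blew up; carries the offending cell and time."""

    def __init__(self, cell: int, time_ms: float):
        self.cell = cell
        self.time_ms = time_ms
        super().__init__(
            f"membrane potential diverged at cell {cell}, t = {time_ms:.3f} ms"
        )


class CalibrationError(PvstrandError, RuntimeError):
    """A calibration bracket fails to straddle its target."""


class MeasurementError(PvstrandError, RuntimeError):
    """A conduction measurement cannot be formed (block, infinite CV)."""
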