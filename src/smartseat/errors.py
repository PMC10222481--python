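"""Exception hierarchy for the smart-seat monitoring stack."""

from __future__ import annotations


class SmartSeatError(Exception):
    """Base class for all package-specific errors."""


class FrameError(SmartSeatError):
    """A serial frame line could not be parsed."""


class CountRangeError(SmartSeatError):
    """An ADC count is outside [0, 2^bits - 1] — corrupt frame."""

    def __init__(self, message: str, sensor: str | None = None):
        super().__init__(message)
        self.sensor = sensor


class SaturationError(SmartSeatError):
    """Measured voltage is at or beyond the divider saturation guard.

    Indicates a shorted sensor or an invalid frame; carries the offending
    sensor label when raised from a per-frame conversion.
    """

    def __init__(self, message: str, sensor: str | None = None):
        super().__init__(message)
        self.sensor = sensor


class ContractError(SmartSeatError):
    """An in-process call violated a module contract (wrong sensor label,
    mismatched ticks, incomplete filter consumed, ...)."""


class InvalidReferenceError(SmartSeatError):
    """Initialization reference missing or below the seated-force guard."""


class InitializationError(SmartSeatError):
    """Session initialization failed (user not seated / sensor fault)."""

    def __init__(self, message: str, sensors: tuple[str, ...] = ()):
        super().__init__(message)
        self.sensors = sensors


class ConnectionLostError(SmartSeatError):
    """The frame stream ended or degraded beyond the retry budget."""


class ConsentError(SmartSeatError):
    """Attempt to persist data for a user without recorded consent."""


class StoreIntegrityError(SmartSeatError):
    """The event store detected an invariant violation (e.g. two
    consecutive shift events in the same direction)."""


class UnknownUserError(SmartSeatError):
    """The requested user does not exist in the store."""


class StoreUnavailableError(SmartSeatError):
    """The event sink cannot currently accept writes."""
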