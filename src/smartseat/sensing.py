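"""Sensor read-out model: ADC counts → voltage → conductance → force.

The seat carries four force sensing resistors, one per quadrant, labelled
``Lt`` (left-top), ``Lb`` (left-bottom), ``Rt`` (right-top), ``Rb``
(right-bottom).  Each sensor sits in a voltage divider with a fixed
resistor of known conductance ``G``; the microcontroller samples the
divider voltage ``V_m`` and ships it as an ADC count.  Decoding inverts
the chain:

    counts → V_m = counts * V_DC / (2^bits - 1)
    V_m    → G_sens = G * V_m / (V_DC - V_m)
    G_sens → F = (G_sens - intercept) / slope        (calibration line)
    F      → u = accuracy_fraction * F / sqrt(3)     (type-B uncertainty)

The forward path (force → counts) is used by the simulator.

Serial frame dialect: one ASCII line per tick,
``<tick>,<Lt>,<Lb>,<Rt>,<Rb>`` with base-10 integer counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

from .config import ReadoutConfig
from .errors import CountRangeError, FrameError, SaturationError

#: Canonical sensor order — left-top, left-bottom, right-top, right-bottom.
SENSOR_ORDER: tuple[str, ...] = ("Lt", "Lb", "Rt", "Rb")


@dataclass(frozen=True)
class RawSample:
    """One frame of four ADC counts at a sampling tick."""

    tick_index: int
    timestamp: float  # seconds since session start, tick * sampling_interval
    counts: Mapping[str, int]  # keyed by SENSOR_ORDER labels

    def __post_init__(self) -> None:
        if self.tick_index < 0:
            raise ValueError("tick_index must be >= 0")
        missing = set(SENSOR_ORDER) - set(self.counts)
        if missing:
            raise ValueError(f"missing sensors in frame: {sorted(missing)}")


@dataclass(frozen=True)
class ForceReading:
    """A per-sensor force value with its type-B standard uncertainty.

    ``below_range`` marks readings whose conductance fell below the
    calibration intercept (unloaded sensor); the force is clamped to 0 N.
    """

    sensor: str
    value: float  # N
    uncertainty: float  # N
    tick_index: int
    below_range: bool = False


def counts_to_voltage(counts: int, cfg: ReadoutConfig) -> float:
    """Convert an ADC count to the measured divider voltage (volts)."""
    if not 0 <= counts <= cfg.adc_max:
        raise CountRangeError(
            f"ADC count {counts} outside [0, {cfg.adc_max}] — corrupt frame"
        )
    return counts * cfg.supply_voltage / cfg.adc_max


def voltage_to_conductance(v_m: float, cfg: ReadoutConfig) -> float:
    """Invert the voltage divider: ``G_sens = G * V_m / (V_DC - V_m)``.

    Voltages within one guard band of the supply rail mean the sensor
    branch is effectively shorted (or the frame invalid) and raise
    :class:`SaturationError` rather than diverging.
    """
    if not math.isfinite(v_m) or v_m < 0:
        raise ValueError(f"measured voltage must be finite and >= 0, got {v_m}")
    if v_m >= cfg.saturation_voltage:
        raise SaturationError(
            f"measured voltage {v_m:.4f} V at/above saturation guard "
            f"{cfg.saturation_voltage:.4f} V"
        )
    return cfg.ref_conductance * v_m / (cfg.supply_voltage - v_m)


def conductance_to_force(g: float, cfg: ReadoutConfig) -> float:
    """Invert the calibration line: ``F = (G - intercept) / slope``.

    Conductances below the intercept correspond to an unloaded sensor;
    the calibration line is a fit over the loaded range, so the force is
    clamped to 0 N there (use :func:`below_calibration_range` to detect it).
    """
    if not math.isfinite(g) or g < 0:
        raise ValueError(f"conductance must be finite and >= 0, got {g}")
    if g < cfg.cal_intercept:
        return 0.0
    return (g - cfg.cal_intercept) / cfg.cal_slope


def below_calibration_range(g: float, cfg: ReadoutConfig) -> bool:
    """True when the conductance falls below the calibration intercept."""
    return g < cfg.cal_intercept


def force_to_conductance(f: float, cfg: ReadoutConfig) -> float:
    """Forward calibration line: ``G = slope * F + intercept`` (μS)."""
    if not math.isfinite(f) or f < 0:
        raise ValueError(f"force must be finite and >= 0, got {f}")
    return cfg.cal_slope * f + cfg.cal_intercept


def type_b_uncertainty(f: float, cfg: ReadoutConfig) -> float:
    """Type-B standard uncertainty of a force reading, N.

    The datasheet accuracy ``a = accuracy_fraction * F`` is converted to a
    standard uncertainty assuming a uniform distribution: ``u = a / sqrt(3)``.
    """
    if not math.isfinite(f) or f < 0:
        raise ValueError(f"force must be finite and >= 0, got {f}")
    return cfg.accuracy_fraction * f / math.sqrt(3.0)


def sample_to_readings(sample: RawSample, cfg: ReadoutConfig) -> dict[str, ForceReading]:
    """Decode one frame into four :class:`ForceReading`, preserving labels.

    Saturation/range errors are re-raised tagged with the offending sensor.
    """
    readings: dict[str, ForceReading] = {}
    for sensor in SENSOR_ORDER:
        try:
            v = counts_to_voltage(sample.counts[sensor], cfg)
            g = voltage_to_conductance(v, cfg)
        except CountRangeError as exc:
            raise CountRangeError(f"sensor {sensor}: {exc}", sensor=sensor) from exc
        except SaturationError as exc:
            raise SaturationError(f"sensor {sensor}: {exc}", sensor=sensor) from exc
        f = conductance_to_force(g, cfg)
        readings[sensor] = ForceReading(
            sensor=sensor,
            value=f,
            uncertainty=type_b_uncertainty(f, cfg),
            tick_index=sample.tick_index,
            below_range=below_calibration_range(g, cfg),
        )
    return readings


# -- serial frame dialect ----------------------------------------------


def format_frame(sample: RawSample) -> str:
    """Render a frame in the serial line dialect (no trailing newline)."""
    counts = ",".join(str(sample.counts[s]) for s in SENSOR_ORDER)
    return f"{sample.tick_index},{counts}"


def parse_frame(line: str, cfg: ReadoutConfig) -> RawSample:
    """Parse one serial line into a :class:`RawSample`.

    Tolerates trailing whitespace; anything else malformed raises
    :class:`FrameError`.  Counts are range-checked against the ADC width.
    """
    fields = line.strip().split(",")
    if len(fields) != 1 + len(SENSOR_ORDER):
        raise FrameError(f"expected 5 comma-separated fields, got {line!r}")
    try:
        values = [int(field) for field in fields]
    except ValueError as exc:
        raise FrameError(f"non-integer field in frame {line!r}") from exc
    tick = values[0]
    if tick < 0:
        raise FrameError(f"negative tick index in frame {line!r}")
    counts = dict(zip(SENSOR_ORDER, values[1:]))
    for sensor, count in counts.items():
        if not 0 <= count <= cfg.adc_max:
            raise FrameError(
                f"sensor {sensor} count {count} outside [0, {cfg.adc_max}] "
                f"in frame {line!r}"
            )
    return RawSample(
        tick_index=tick, timestamp=tick * cfg.sampling_interval, counts=counts
    )


def iter_frames(lines: Iterable[str], cfg: ReadoutConfig) -> Iterator[RawSample]:
    """Parse a line stream, silently skipping blank lines.

    Malformed lines raise :class:`FrameError`; callers that need the
    skip-and-count behaviour (the session loop) catch it per line.
    """
    for line in lines:
        if not line.strip():
            continue
        yield parse_frame(line, cfg)
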