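"""Synthetic seat: four-sensor force traces and serial frames.

Stands in for the physical cushion, the sensors and the microcontroller.
A seated person of total seat load ``W`` is modelled as a two-way split:
a fraction ``top_fraction`` of ``W`` on the front (top) sensor pair and
the rest on the rear (bottom) pair, each pair split left/right by its own
fraction.  Postures move the left/right fractions:

* leaning forward left/right shifts the *top* pair's split by ±lean_delta;
* leaning backward left/right shifts the *bottom* pair's split by ±lean_delta;
* crossing a leg shifts the *bottom* split by ±cross_delta and raises
  ``top_fraction`` slightly (the knee angle pulls load forward).

On top of the posture model the generator applies per-sensor response
gains (fabrication variability), multiplicative Gaussian noise, optional
brief transients, and the full forward sensing chain (calibration line →
voltage divider → ADC quantization) to emit serial frames.  Everything is
reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .config import ReadoutConfig
from .sensing import SENSOR_ORDER, RawSample, force_to_conductance, format_frame

logger = logging.getLogger(__name__)

POSTURE_LABELS: tuple[str, ...] = (
    "symmetric",
    "lean_fwd_left",
    "lean_fwd_right",
    "lean_back_left",
    "lean_back_right",
    "cross_left_leg",
    "cross_right_leg",
)

#: The six incorrect postures of the test protocol, in order.
INCORRECT_POSTURES: tuple[str, ...] = POSTURE_LABELS[1:]


@dataclass(frozen=True)
class PostureScenario:
    """A posture held for a number of ticks, as seat-load fractions."""

    label: str
    left_fraction_top: float
    left_fraction_bottom: float
    top_fraction: float
    duration_ticks: int

    def __post_init__(self) -> None:
        for name in ("left_fraction_top", "left_fraction_bottom", "top_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be strictly inside (0, 1), got {v}")
        if self.duration_ticks < 1:
            raise ValueError("duration_ticks must be >= 1")


def make_scenario(
    label: str,
    duration_ticks: int,
    *,
    top_fraction: float = 0.6,
    lean_delta: float = 0.20,
    cross_delta: float = 0.25,
    knee_shift: float = 0.05,
) -> PostureScenario:
    """Build a scenario from a posture label and the split deltas."""
    lt, lb, top = 0.5, 0.5, top_fraction
    if label == "symmetric":
        pass
    elif label == "lean_fwd_left":
        lt = 0.5 + lean_delta
    elif label == "lean_fwd_right":
        lt = 0.5 - lean_delta
    elif label == "lean_back_left":
        lb = 0.5 + lean_delta
    elif label == "lean_back_right":
        lb = 0.5 - lean_delta
    elif label == "cross_left_leg":
        lb = 0.5 + cross_delta
        top = top_fraction + knee_shift
    elif label == "cross_right_leg":
        lb = 0.5 - cross_delta
        top = top_fraction + knee_shift
    else:
        raise ValueError(f"unknown posture label {label!r}")
    return PostureScenario(
        label=label,
        left_fraction_top=lt,
        left_fraction_bottom=lb,
        top_fraction=top,
        duration_ticks=duration_ticks,
    )


@dataclass(frozen=True)
class Transient:
    """A brief additive force spike on one sensor (a quick movement)."""

    tick: int
    sensor: str
    magnitude: float  # N, added to that sensor
    width: int = 1  # ticks


@dataclass(frozen=True)
class SimulationConfig:
    """Sitter and sensor-array model for trace generation.

    ``total_force`` is the seat load of the simulated sitter (N);
    ``noise_fraction`` the per-tick multiplicative Gaussian noise scale
    (kept below the 2.5% accuracy bound by default); ``sensor_gain`` the
    per-sensor response multipliers emulating fabrication variability.
    """

    total_force: float = 400.0
    noise_fraction: float = 0.01
    sensor_gain: dict[str, float] = field(
        default_factory=lambda: {s: 1.0 for s in SENSOR_ORDER}
    )
    transients: tuple[Transient, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_force <= 0:
            raise ValueError("total_force must be > 0")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if any(g <= 0 for g in self.sensor_gain.values()):
            raise ValueError("sensor gains must be > 0")


def posture_to_forces(
    scenario: PostureScenario, sim: SimulationConfig
) -> dict[str, float]:
    """Noise-free per-sensor forces for a posture; they sum to total_force."""
    w = sim.total_force
    top = w * scenario.top_fraction
    bottom = w - top
    return {
        "Lt": top * scenario.left_fraction_top,
        "Rt": top * (1.0 - scenario.left_fraction_top),
        "Lb": bottom * scenario.left_fraction_bottom,
        "Rb": bottom * (1.0 - scenario.left_fraction_bottom),
    }


def generate_trace(
    schedule: Sequence[PostureScenario],
    sim: SimulationConfig,
    cfg: ReadoutConfig,
    start_tick: int = 0,
) -> Iterator[RawSample]:
    """Generate raw ADC frames for a posture schedule.

    Per tick: posture forces + scheduled transients, per-sensor gains,
    multiplicative Gaussian noise, then the forward chain — calibration
    line, divider voltage ``v = V_DC * G_s / (G + G_s)``, mid-tread ADC
    quantization.  Counts that would quantize into the saturation guard
    band are clipped (with a warning) so every emitted frame decodes.
    """
    if not schedule:
        raise ValueError("schedule must contain at least one scenario")
    rng = np.random.default_rng(sim.seed)
    ceiling = cfg.adc_max - 2  # stay below the saturation guard
    tick = start_tick
    for scenario in schedule:
        base = posture_to_forces(scenario, sim)
        for _ in range(scenario.duration_ticks):
            noise = rng.standard_normal(len(SENSOR_ORDER))
            counts = {}
            for i, sensor in enumerate(SENSOR_ORDER):
                f = base[sensor]
                for tr in sim.transients:
                    if tr.sensor == sensor and tr.tick <= tick < tr.tick + tr.width:
                        f += tr.magnitude
                f *= sim.sensor_gain[sensor]
                f *= 1.0 + sim.noise_fraction * noise[i]
                f = max(f, 0.0)
                g = force_to_conductance(f, cfg)
                v = cfg.supply_voltage * g / (cfg.ref_conductance + g)
                c = int(round(v / cfg.supply_voltage * cfg.adc_max))
                if c > ceiling:
                    logger.warning(
                        "tick %d sensor %s saturated (count %d), clipped to %d",
                        tick,
                        sensor,
                        c,
                        ceiling,
                    )
                    c = ceiling
                counts[sensor] = c
            yield RawSample(
                tick_index=tick,
                timestamp=tick * cfg.sampling_interval,
                counts=counts,
            )
            tick += 1


def six_posture_schedule(
    *,
    hold_ticks: int = 5,
    posture_ticks: int = 20,
    recovery_ticks: int = 20,
    top_fraction: float = 0.6,
    lean_delta: float = 0.20,
    cross_delta: float = 0.25,
) -> list[PostureScenario]:
    """The test protocol: hold correct posture, then each of the six
    incorrect postures followed by a return to the correct one."""
    deltas = dict(
        top_fraction=top_fraction, lean_delta=lean_delta, cross_delta=cross_delta
    )
    schedule = [make_scenario("symmetric", hold_ticks, **deltas)]
    for label in INCORRECT_POSTURES:
        schedule.append(make_scenario(label, posture_ticks, **deltas))
        schedule.append(make_scenario("symmetric", recovery_ticks, **deltas))
    return schedule


def six_posture_protocol(
    sim: SimulationConfig,
    cfg: ReadoutConfig,
    **schedule_kwargs,
) -> Iterator[RawSample]:
    """Frames for the six-posture protocol (see six_posture_schedule)."""
    return generate_trace(six_posture_schedule(**schedule_kwargs), sim, cfg)


# -- scenario schedule files -------------------------------------------


def parse_schedule(
    lines: Iterable[str],
    *,
    top_fraction: float = 0.6,
    cross_delta: float = 0.25,
) -> list[PostureScenario]:
    """Parse a schedule file: one ``<label> <ticks> [lean_delta]`` per line.

    Blank lines and ``#`` comments are skipped; the optional third field
    overrides lean_delta (and cross_delta for the leg-cross postures).
    Errors name the offending line number.
    """
    schedule: list[PostureScenario] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (2, 3):
            raise ValueError(
                f"schedule line {lineno}: expected '<label> <ticks> [delta]', "
                f"got {raw!r}"
            )
        label = fields[0]
        if label not in POSTURE_LABELS:
            raise ValueError(f"schedule line {lineno}: unknown posture {label!r}")
        try:
            ticks = int(fields[1])
            delta = float(fields[2]) if len(fields) == 3 else 0.20
        except ValueError as exc:
            raise ValueError(f"schedule line {lineno}: bad number in {raw!r}") from exc
        schedule.append(
            make_scenario(
                label,
                ticks,
                top_fraction=top_fraction,
                lean_delta=delta,
                cross_delta=delta if len(fields) == 3 else cross_delta,
            )
        )
    return schedule


def load_schedule(path: str | Path, **kwargs) -> list[PostureScenario]:
    return parse_schedule(Path(path).read_text().splitlines(), **kwargs)


def format_frame_stream(
    schedule: Sequence[PostureScenario],
    sim: SimulationConfig,
    cfg: ReadoutConfig,
) -> str:
    """Render a whole schedule as serial-dialect text (one frame per line)."""
    return (
        "\n".join(format_frame(s) for s in generate_trace(schedule, sim, cfg)) + "\n"
    )
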