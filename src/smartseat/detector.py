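"""Normalization and interval-overlap asymmetry detection.

Each sensor's filtered force is divided by the reference captured during
initialization while the sitter holds the correct posture, so a correctly
seated user reads ≈ 1 on every sensor regardless of per-sensor response
variability.  Asymmetry is assessed per left/right pair — top pair and
bottom pair independently, never across — by checking whether the
uncertainty intervals of the two normalized readings intersect.  The
posture is flagged asymmetric when at least one of four strict interval
separations holds:

    n-Rt_upper < n-Lt_lower   (top, left heavy)
    n-Rb_upper < n-Lb_lower   (bottom, left heavy)
    n-Lt_upper < n-Rt_lower   (top, right heavy)
    n-Lb_upper < n-Rb_lower   (bottom, right heavy)

Touching intervals count as overlap (symmetric).  Front/rear load shifts
(e.g. changing knee angle) never trigger the flag because top and bottom
pairs are compared separately.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping

from .config import ReadoutConfig
from .errors import ContractError, InvalidReferenceError
from .filtering import FilteredForce
from .sensing import SENSOR_ORDER

#: Condition labels, in the order the four comparisons are evaluated.
CONDITIONS: tuple[str, ...] = (
    "top_left_heavy",
    "bottom_left_heavy",
    "top_right_heavy",
    "bottom_right_heavy",
)


@dataclass(frozen=True)
class ReferenceProfile:
    """Per-sensor reference forces captured at initialization.

    ``uncertainties`` holds the propagated uncertainty of each reference
    mean; it is only consulted when ``propagate_reference_uncertainty``
    is enabled in the configuration.
    """

    forces: Mapping[str, float]  # N, keyed by sensor label
    uncertainties: Mapping[str, float] = field(default_factory=dict)
    created_at: float = 0.0  # seconds since session start

    def validate(self, cfg: ReadoutConfig) -> None:
        """Raise unless every sensor has a plausible seated reference."""
        for sensor in SENSOR_ORDER:
            ref = self.forces.get(sensor)
            if ref is None:
                raise InvalidReferenceError(f"no reference for sensor {sensor}")
            if not math.isfinite(ref) or ref < cfg.min_seated_force:
                raise InvalidReferenceError(
                    f"reference for sensor {sensor} is {ref!r} N, below the "
                    f"seated-force guard {cfg.min_seated_force} N"
                )


@dataclass(frozen=True)
class NormalizedReading:
    """Filtered force scaled by the initialization reference (dimensionless)."""

    sensor: str
    n_value: float
    n_lower: float
    n_upper: float
    tick_index: int


class Direction(enum.Enum):
    TO_ASYMMETRIC = "ToAsymmetric"
    TO_SYMMETRIC = "ToSymmetric"


@dataclass(frozen=True)
class PostureFlag:
    """Boolean asymmetry decision at one tick, with the conditions that fired."""

    tick_index: int
    asymmetric: bool
    triggered_conditions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.asymmetric != bool(self.triggered_conditions):
            raise ContractError(
                "asymmetric flag must equal non-emptiness of triggered conditions"
            )


@dataclass(frozen=True)
class ShiftEvent:
    """A symmetric ↔ asymmetric transition of the posture flag."""

    tick_index: int
    timestamp: float  # seconds since session start
    direction: Direction
    triggered_conditions: frozenset[str] = frozenset()
    session_id: str | None = None
    user_id: int | None = None


def normalize(
    filtered: FilteredForce, reference: ReferenceProfile, cfg: ReadoutConfig
) -> NormalizedReading:
    """Scale a filtered force by its sensor's initialization reference.

    The reference is treated as an exact scale factor; with
    ``propagate_reference_uncertainty`` on, its own uncertainty is folded
    into the normalized half-width in quadrature.
    """
    if not filtered.complete:
        raise ContractError(
            f"normalize() requires a complete moving average "
            f"(sensor {filtered.sensor}, tick {filtered.tick_index})"
        )
    ref = reference.forces.get(filtered.sensor)
    if ref is None or not math.isfinite(ref) or ref < cfg.min_seated_force:
        raise InvalidReferenceError(
            f"invalid reference {ref!r} N for sensor {filtered.sensor}"
        )
    n_value = filtered.mean / ref
    half = filtered.uncertainty / ref
    if cfg.propagate_reference_uncertainty:
        u_ref = reference.uncertainties.get(filtered.sensor, 0.0)
        half = math.sqrt(half * half + (n_value * u_ref / ref) ** 2)
    return NormalizedReading(
        sensor=filtered.sensor,
        n_value=n_value,
        n_lower=n_value - half,
        n_upper=n_value + half,
        tick_index=filtered.tick_index,
    )


def asymmetry_flag(
    n_lt: NormalizedReading,
    n_lb: NormalizedReading,
    n_rt: NormalizedReading,
    n_rb: NormalizedReading,
) -> PostureFlag:
    """Evaluate the four-condition interval-overlap test at one tick.

    Strict inequalities: two intervals that merely touch still overlap and
    the posture stays symmetric.  Top and bottom pairs are independent.
    """
    readings = (n_lt, n_lb, n_rt, n_rb)
    ticks = {r.tick_index for r in readings}
    if len(ticks) != 1:
        raise ContractError(f"mismatched tick indices in flag evaluation: {ticks}")
    labels = [r.sensor for r in readings]
    if labels != ["Lt", "Lb", "Rt", "Rb"]:
        raise ContractError(f"sensor labels out of order: {labels}")
    fired = []
    if n_rt.n_upper < n_lt.n_lower:
        fired.append("top_left_heavy")
    if n_rb.n_upper < n_lb.n_lower:
        fired.append("bottom_left_heavy")
    if n_lt.n_upper < n_rt.n_lower:
        fired.append("top_right_heavy")
    if n_lb.n_upper < n_rb.n_lower:
        fired.append("bottom_right_heavy")
    return PostureFlag(
        tick_index=ticks.pop(),
        asymmetric=bool(fired),
        triggered_conditions=frozenset(fired),
    )


def detect_transition(
    previous: PostureFlag | None,
    current: PostureFlag,
    sampling_interval: float = 0.5,
) -> ShiftEvent | None:
    """Emit a shift event when the flag changes state, else None.

    The first evaluated flag is compared against an assumed-symmetric
    baseline: initialization requires the sitter to hold the correct
    posture, so the session starts symmetric by construction.
    """
    if previous is not None and current.tick_index <= previous.tick_index:
        raise ContractError(
            f"non-monotone ticks: {previous.tick_index} -> {current.tick_index}"
        )
    was_asymmetric = previous.asymmetric if previous is not None else False
    if current.asymmetric == was_asymmetric:
        return None
    direction = (
        Direction.TO_ASYMMETRIC if current.asymmetric else Direction.TO_SYMMETRIC
    )
    return ShiftEvent(
        tick_index=current.tick_index,
        timestamp=current.tick_index * sampling_interval,
        direction=direction,
        triggered_conditions=current.triggered_conditions
        if current.asymmetric
        else frozenset(),
    )
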