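"""Per-sensor circular queue and 5-point moving average with uncertainty.

The moving average is a low-pass filter: musculoskeletal risk comes from
prolonged static loading, not from brief movements, so the monitor should
respond to sustained asymmetry and ignore single-tick spikes (a spike of
magnitude ``m`` perturbs the mean by exactly ``m/n`` for ``n`` ticks).

Two uncertainty propagation modes exist for the mean of ``n`` readings
with per-reading type-B uncertainties ``u_i``:

* ``mean`` (default): ``u = sqrt(sum u_i^2) / n`` — the standard
  propagation for an unweighted mean of independent readings.
* ``sum``: ``u = sqrt(sum u_i^2)`` — the literal root-sum-square used by
  the reference device; intervals are sqrt(n)·wider, so the asymmetry
  test is more conservative (fewer flags).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterator

from .config import ReadoutConfig
from .errors import ContractError
from .sensing import ForceReading


class CircularQueue:
    """Fixed-capacity FIFO of force readings for one sensor.

    Pushing onto a full queue evicts exactly the oldest entry; iteration
    runs oldest → newest.
    """

    def __init__(self, capacity: int = 5, sensor: str | None = None):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self.sensor = sensor
        self._entries: deque[ForceReading] = deque(maxlen=capacity)

    @property
    def fill_count(self) -> int:
        return len(self._entries)

    @property
    def is_full(self) -> bool:
        return len(self._entries) == self.capacity

    def push(self, reading: ForceReading) -> ForceReading | None:
        """Append a reading; return the evicted entry, if any."""
        if self.sensor is not None and reading.sensor != self.sensor:
            raise ContractError(
                f"queue for sensor {self.sensor} got reading for {reading.sensor}"
            )
        evicted = self._entries[0] if self.is_full else None
        self._entries.append(reading)
        return evicted

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[ForceReading]:
        return iter(self._entries)


@dataclass(frozen=True)
class FilteredForce:
    """Moving-average force with propagated uncertainty and bounds.

    ``complete`` is False while the queue is still warming up; downstream
    consumers (the asymmetry detector) must ignore incomplete values.
    """

    sensor: str
    mean: float  # N
    uncertainty: float  # N
    lower: float  # N, mean - uncertainty
    upper: float  # N, mean + uncertainty
    complete: bool
    tick_index: int


def push_and_filter(
    queue: CircularQueue, reading: ForceReading, cfg: ReadoutConfig
) -> FilteredForce:
    """Push a reading and return the updated moving average.

    The mean and the root-sum-square run over the entries currently held
    (oldest → newest); during warm-up they cover the partial fill and the
    result is marked ``complete=False``.
    """
    queue.push(reading)
    n = queue.fill_count
    total = 0.0
    sq = 0.0
    for entry in queue:
        total += entry.value
        sq += entry.uncertainty * entry.uncertainty
    mean = total / n
    rss = math.sqrt(sq)
    if cfg.uncertainty_propagation == "mean":
        u = rss / n
    else:  # "sum": literal root-sum-square
        u = rss
    return FilteredForce(
        sensor=reading.sensor,
        mean=mean,
        uncertainty=u,
        lower=mean - u,
        upper=mean + u,
        complete=queue.is_full,
        tick_index=reading.tick_index,
    )


def bounds(filtered: FilteredForce) -> tuple[float, float]:
    """Return the (lower, upper) uncertainty bounds of the filtered force."""
    return filtered.lower, filtered.upper


def filtered_csv_header() -> str:
    return "tick,sensor,mean,uncertainty,lower,upper,complete"


def filtered_csv_row(f: FilteredForce) -> str:
    return (
        f"{f.tick_index},{f.sensor},{f.mean!r},{f.uncertainty!r},"
        f"{f.lower!r},{f.upper!r},{f.complete}"
    )
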