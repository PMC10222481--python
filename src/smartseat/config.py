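"""Configuration of the acquisition chain.

All physical and algorithmic constants of the read-out live in
:class:`ReadoutConfig`: the FSR calibration line (conductance vs. force),
the voltage-divider constants, the ADC resolution, the datasheet accuracy
fraction used for type-B uncertainty, the sampling cadence and the filter
queue length.  Defaults reproduce the reference device: a DF9-40 force
sensing resistor read through a 100 μS divider resistor at 3.3 V on a
10-bit ADC, sampled every 500 ms and smoothed with a 5-entry queue.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, model_validator


class ReadoutConfig(BaseModel):
    """Physical and algorithmic constants of the acquisition chain.

    Parameters
    ----------
    cal_slope
        Slope of the sensor calibration line, μS per newton.  The sensor
        conductance is modelled as ``G = cal_slope * F + cal_intercept``.
    cal_intercept
        Conductance at zero force, μS.
    supply_voltage
        DC bias of the divider, volts.
    ref_conductance
        Conductance of the fixed divider resistor, μS.
    adc_bits
        ADC resolution; counts span ``0 .. 2**adc_bits - 1``.
    accuracy_fraction
        Relative datasheet accuracy ``a/F`` of a force reading; the type-B
        standard uncertainty of a reading is ``accuracy_fraction * F / sqrt(3)``
        (uniform-distribution assumption).
    sampling_interval
        Seconds between frames.
    queue_length
        Moving-average window (entries in the circular queue).
    min_seated_force
        Initialization guard, N: every per-sensor reference must exceed it,
        otherwise the user is not seated or a sensor is faulty.
    uncertainty_propagation
        ``"mean"`` propagates the uncertainty of the unweighted mean,
        ``u = sqrt(sum u_i^2) / n`` (metrologically standard);
        ``"sum"`` keeps the literal root-sum-square ``u = sqrt(sum u_i^2)``
        of the reference device, giving wider, more conservative intervals.
    propagate_reference_uncertainty
        When true, the stored reference's own uncertainty is folded (in
        quadrature) into normalized bounds; off by default — the reference
        is treated as an exact scale factor.
    saturation_margin_counts
        Width of the saturation guard band below full scale, in ADC counts.
    """

    cal_slope: float = Field(default=0.950, gt=0)
    cal_intercept: float = Field(default=9.848, ge=0)
    supply_voltage: float = Field(default=3.3, gt=0)
    ref_conductance: float = Field(default=100.0, gt=0)
    adc_bits: int = Field(default=10, ge=1, le=16)
    accuracy_fraction: float = Field(default=0.025, gt=0, lt=1)
    sampling_interval: float = Field(default=0.5, gt=0)
    queue_length: int = Field(default=5, ge=1)
    min_seated_force: float = Field(default=10.0, gt=0)
    uncertainty_propagation: Literal["mean", "sum"] = "mean"
    propagate_reference_uncertainty: bool = False
    saturation_margin_counts: float = Field(default=1.0, gt=0)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_margin(self) -> "ReadoutConfig":
        if self.saturation_margin_counts >= self.adc_max:
            raise ValueError("saturation margin must be below full scale")
        return self

    @property
    def adc_max(self) -> int:
        """Full-scale ADC count, ``2**adc_bits - 1``."""
        return (1 << self.adc_bits) - 1

    @property
    def lsb_voltage(self) -> float:
        """Voltage width of one ADC count."""
        return self.supply_voltage / self.adc_max

    @property
    def saturation_voltage(self) -> float:
        """Voltages at or above this value are treated as saturated."""
        return self.supply_voltage - self.saturation_margin_counts * self.lsb_voltage

    # -- flat key-value config file -------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "ReadoutConfig":
        """Load from a flat ``key = value`` file (``#`` starts a comment)."""
        values: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        """Write all fields as a flat ``key = value`` file."""
        lines = [f"{name} = {getattr(self, name)}" for name in type(self).model_fields]
        Path(path).write_text("\n".join(lines) + "\n")


DEFAULT_CONFIG = ReadoutConfig()
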