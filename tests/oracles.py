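"""Independent batch oracles used by the test suite.

These recompute, from a recorded raw trace and first principles, the
quantities the streaming pipeline produces tick by tick: the decode
chain as one closed-form expression, the moving averages over explicit
window slices, the normalized bounds and the four interval comparisons.
They share no code with the package's streaming path.
"""

from __future__ import annotations

import math

SENSORS = ("Lt", "Lb", "Rt", "Rb")


def decode_force(count: int, cfg) -> float:
    """Single-expression decode: counts → volts → μS → N (clamped)."""
    v = count * cfg.supply_voltage / ((1 << cfg.adc_bits) - 1)
    g = cfg.ref_conductance * v / (cfg.supply_voltage - v)
    return max((g - cfg.cal_intercept) / cfg.cal_slope, 0.0)


def batch_run(frames, cfg):
    """Recompute every flag and event of a session from the raw trace.

    The first ``queue_length`` frames are the initialization hold; the
    reference is the window mean at the last of them.  Returns
    ``(flags, events)`` where flags is a list of (tick, bool) for each
    monitoring tick and events a list of (tick, direction-string).
    """
    n = cfg.queue_length
    forces = {s: [decode_force(f.counts[s], cfg) for f in frames] for s in SENSORS}
    uncs = {
        s: [cfg.accuracy_fraction * x / math.sqrt(3.0) for x in forces[s]]
        for s in SENSORS
    }

    def window_stats(s, t):
        lo = max(0, t - n + 1)
        total = 0.0
        for x in forces[s][lo : t + 1]:
            total += x
        mean = total / (t + 1 - lo)
        sq = 0.0
        for u in uncs[s][lo : t + 1]:
            sq += u * u
        rss = math.sqrt(sq)
        u = rss / (t + 1 - lo) if cfg.uncertainty_propagation == "mean" else rss
        return mean, u

    reference = {s: window_stats(s, n - 1)[0] for s in SENSORS}

    flags = []
    events = []
    previous = False
    for t in range(n, len(frames)):
        bounds = {}
        for s in SENSORS:
            mean, u = window_stats(s, t)
            ref = reference[s]
            bounds[s] = ((mean - u) / ref, (mean + u) / ref)
        asym = (
            bounds["Rt"][1] < bounds["Lt"][0]
            or bounds["Rb"][1] < bounds["Lb"][0]
            or bounds["Lt"][1] < bounds["Rt"][0]
            or bounds["Lb"][1] < bounds["Rb"][0]
        )
        tick = frames[t].tick_index
        flags.append((tick, asym))
        if asym != previous:
            events.append((tick, "ToAsymmetric" if asym else "ToSymmetric"))
        previous = asym
    return flags, events
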