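# Methods

## Measurement model

Four force-sensing resistors (FSRs) sit under the left/right × front/rear
quadrants of a seat cushion, labelled `Lt, Lb, Rt, Rb`. An FSR's
conductance grows approximately linearly with applied force over its
working range; we model it as `G_sens = m·F + b` with defaults
`m = 0.950 μS/N`, `b = 9.848 μS` (the fitted calibration of the reference
device's DF9-40 sensors). The calibration pair is configurable so that a
differently fitted sensor — or a kgf-based calibration — can be swapped
in; the detector is scale-free after normalization, so the force unit
cancels.

Read-out is a voltage divider: the sensor in series with a fixed resistor
of conductance `G = 100 μS` at `V_DC = 3.3 V`, sampled by a 10-bit ADC
every `Δt = 500 ms`. Decoding inverts
`G_sens = G·V_m/(V_DC − V_m)` and then the calibration line.

Numerical guards:

* **Saturation.** `V_m → V_DC` makes the divider inversion diverge. A
  guard band of one ADC count below full scale (configurable) raises a
  saturation error naming the sensor; the session treats it as a frame
  error, skips the tick, and marks the sensor unhealthy.
* **Below-intercept clamp.** The calibration line is a fit over the
  loaded range, so conductances below the intercept (unloaded sensor)
  would decode to negative force. They are clamped to 0 N and flagged
  `below_range` instead — unphysical negatives never propagate.
* **ADC model.** Mid-tread quantization,
  `counts = round(v·(2^bits − 1)/V_DC)`, used only on the simulator's
  forward path.

## Uncertainty

Each reading's type-B standard uncertainty comes from the manufacturer
accuracy `a = 2.5%·F` under a uniform-distribution assumption:
`u = a/√3 ≈ 1.44%·F`. Uncertainty is evaluated in the force domain, not
on conductance or voltage.

The 5-point moving average supports two propagation modes:

* `mean` (default): `u = √(Σu_i²)/5 ≈ 0.65%·F` — the standard propagation
  for an unweighted mean of independent readings.
* `sum`: `u = √(Σu_i²) ≈ 3.2%·F` — the literal root-sum-square of the
  reference device's filter; intervals are 5× wider.

The choice matters operationally. The asymmetry flag fires when the
left–right difference of normalized means exceeds the sum of the two
half-widths: ~1.3% under `mean`, ~6.5% under `sum`. Realistic sensor
noise of ~1% per reading leaves the 5-averaged left–right difference with
a standard deviation of ~0.6%, so `mean` puts the trigger threshold at
only ~2σ of the noise — a correctly seated user would be flagged on a few
percent of ticks — while `sum` puts it at ~10σ, making false warnings
negligible at the cost of needing a larger true asymmetry (which the
tested postures exceed many times over). The `mean` default is kept
because it is the metrologically correct uncertainty of the mean;
replications of the device's test protocol, and deployments that
prioritize a quiet warning channel, should run `uncertainty_propagation =
sum`, and the bundled protocol examples and acceptance checks of the
protocol do exactly that. This is a deliberate fidelity-vs-metrology
trade-off, not an oversight.

## Detection

Per-sensor references are the moving averages captured the moment the
5-entry queues first fill, while the user holds a correct posture; this
per-session self-calibration absorbs sensor-to-sensor response spread and
environmental drift (temperature, humidity), and is refreshed every
session (sessions are soft-limited to 2 h, after which the monitor asks
for re-initialization). References below `min_seated_force` (10 N — far
below any seated quadrant load, far above a floating sensor) abort
initialization naming the sensors, distinguishing "nobody seated" and
sensor faults from a legitimate reference.

The reference is treated as an exact scale factor: normalized bounds
derive only from the live measurement's uncertainty. A config switch
(`propagate_reference_uncertainty`) folds the reference's own uncertainty
in quadrature for sensitivity studies; it is off by default.

The flag is the OR of four strict interval separations (left heavy / right
heavy, top pair / bottom pair). Strictness means touching intervals count
as overlap — symmetric. Top and bottom pairs are never compared with each
other: front/rear load redistribution (knee angle) is not left–right
asymmetry and must not alarm. Flag edges become `ToAsymmetric` /
`ToSymmetric` shift events; the baseline after initialization is
symmetric by construction, so event sequences always alternate starting
with `ToAsymmetric`. Warnings are opened on rising edges and closed on
falling edges or session end. No debounce beyond the 5-sample averaging
is applied.

All session time is derived (`tick × Δt`), never read from a clock, so
identical frame streams reproduce identical session records.

## Simulator

The generator emulates a sitter of total seat load `W` (default 400 N)
split `top_fraction` (default 0.6) front vs. rear, each pair split
left/right. Postures move the splits: leaning forward/backward
left/right moves the top/bottom left fraction by ±`lean_delta` (default
0.20); crossing a leg moves the bottom split by ±`cross_delta` (default
0.25) and raises `top_fraction` by 0.05 (the knee pulls load forward).
These magnitudes are plausible stand-ins chosen to exceed the combined
uncertainty intervals at realistic loads — they are configuration, not
biomechanical claims. On top: per-sensor response gains (fabrication
variability), multiplicative Gaussian noise with `σ = 1%·F` per tick
(below the 2.5% accuracy bound), optional single- or multi-tick force
transients, and the full forward chain to quantized ADC frames. Streams
are byte-reproducible from the seed.

What the simulator does **not** model: pressure-distribution geometry,
postural sway spectra (noise is white), sensor drift within a session,
hysteresis and creep of the FSR polymer, or cushion mechanics. Passing
tests therefore demonstrate the correctness of the processing chain and
the detector's decision logic under the stated load-split model — not
clinical detection performance on real sitters.

## Test-protocol replication

The six-posture protocol (hold correct posture for the 5-frame
initialization, then 20 ticks of each incorrect posture followed by 20
ticks correct) is generated with the defaults above under `sum`
propagation and must yield exactly 6 `ToAsymmetric` + 6 `ToSymmetric`
alternating events, each detection within the 5-tick queue transit of its
posture change. The behavioural suite additionally checks: noise-free
symmetric traces never flag over 10,000 ticks of varying front/rear
split; the streaming pipeline equals an independent batch recomputation
from the raw trace, flag for flag and event for event, over 100 random
noisy sessions; calibration encode/decode round-trips over 0–500 N; the
constant-stream filter uncertainty contracts by √5 under `mean`
propagation; and a single-tick transient whose 5-averaged perturbation
stays below the combined interval half-widths (e.g. 6% of `W` for one
tick under `sum`) produces no event. Problem sizes (10,000 ticks, 100
sessions, 245-tick protocol) keep the whole suite under a few seconds
while exercising every code path at the study's stated conditions.

## Persistence

A local SQLite store stands in for the remote monitoring database; the
recording semantics are the contract: explicit consent gating (events of
non-consenting users are processed live for notifications but never
persisted), per-session alternation enforced at the store boundary, event
queries returning `user_id` only, revocation by deletion cascading to all
derived records, and sink outages degrading to local buffering with a
warning rather than stopping the monitor. Behaviour summaries sum
`ToAsymmetric → ToSymmetric` spans per session; a span still open at
session end counts as asymmetric up to the final tick (an edge the
recording semantics leave open; closing it at the end is the conservative
choice for a "time at risk" metric).

## Known limitations

* The serial transport is a line dialect over files/pipes/iterables; no
  hardware serial-port driver is bundled.
* Calibration coefficients are inputs; no fitting from raw calibration
  sweeps.
* The detector classifies symmetric vs. asymmetric only — no named
  posture recognition and no severity grading.
* Simulator realism limits are listed above; defaults are study
  conditions, not measurements of real sitters.
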