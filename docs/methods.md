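# Methods

## Error model

Each device clock is modelled as `t′(t) = t + T_drift(t) + T_off(t)`.
`T_off` (seconds) is whatever offset the last synchronisation left —
identical in distribution across devices with the same hardware —
and `T_drift` is the integral of a signed, piecewise-constant rate in
parts per million.  Drift of real oscillators is not constant (it follows
temperature, supply voltage and ageing); the model captures the dominant
temperature dependence by deriving the rate trajectory from a
piecewise-constant `TemperatureProfile` through a device-specific
temp→ppm curve, and leaves the curve itself to the user because clock
data sheets specify only the envelope (±max ppm over a temperature
range), not the curve.  By default each simulated device draws one
constant rate uniformly from [−max, +max] at scenario build; integration
is then exact, and the rated budget `ppm × 1e-6 × Δt` is a hard bound on
every admissible trajectory.  Crystal physics (parabolic tuning-fork
curves), ageing and voltage dependence are out of scope.

Budget tables use day = 86,400 s, week = 604,800 s and month = 31 days =
2,678,400 s, with ties rounded away from zero — the conventions under
which the per-class worst-case table is internally consistent at its
printed precision.

## Set-time semantics

The RTC is set with full-second resolution and zeroes its milliseconds
field, so firmware waits on a high-accuracy timer until the next full UTC
second of the *estimated* timeline before issuing the 9-byte set command
(0.18 ms at 400 kbit/s I²C).  The post-set offset is therefore exactly
(estimate error) + 0.18 ms, and the drift anchor restarts at the set.
Drift accumulated during the sub-second wait (≤ 3 µs at 3 ppm) is
neglected.  RTC reads floor to the 10 ms resolution; the 5-byte stored
timestamp (big-endian seconds + one byte of 10 ms units) likewise
truncates, so a stored stamp never claims more elapsed time than has
passed.  Big-endianness is our choice (it makes byte order chronological
for sorting); device firmware may differ.

## Synchronisation methods

**GPS (A).**  The module's reported time lags truth by a processing and
transport delay that correlates with the number of visible satellites;
compensation is linear, `delay = c0 + c1·n_sats`, with coefficients as
configuration inputs (defaults 0: they are a per-module calibration, not
a constant of nature).  A fix is required before the time is trusted.

**WiFi/NTP (B).**  One four-timestamp exchange per synchronisation (no
multi-server averaging, to save energy).  The symmetric-delay estimator
is exact when outbound and return delays match and errs by half the
asymmetry otherwise — both facts are closed-form and tested as such.

**Proximity (C).**  The deviation a receiver measures against a sender
is `1000·(own_window_second − msg.utc_second) + (own_rel_at_reception −
airtime_est) − msg.rel`; the UTC-second fields carry whole-second
disagreements and the relative timestamps the sub-second part.  The
airtime correction is applied to the receiver's reception timestamp
(mapping it back to send time); whether the measured 5.2 ms includes
receiver processing is unknowable from outside the firmware, so the
simulator separates the true airtime from the onboard estimate and the
estimator can be stress-tested with a mismatch.  Per (receiver, sender)
pair the median over the ≤8 per-message deviations is used — robust to a
corrupted message; the aggregation is our choice.  The resync rule is
strict: deviation must exceed 50 ms (not equal it).  On equal last-sync
stamps the lowest device id is the reference, a deterministic,
order-independent tie-break.

## Noise models

Synchronisation offsets are drawn from Laplace distributions
parameterised by the measured stationary medians and (unscaled) MADs of
each method — GPS 2.72 ms (MAD 12.47), WiFi/NTP 0.43 ms (MAD 1.51),
proximity 5 ms (MAD 2) — with scale = MAD/ln 2 so the population MAD
equals the reported one.  The family is our choice (only median and MAD
are reported; Laplace is the maximum-entropy-like heavy-tailed default
consistent with MAD reporting and is swappable for normal).  The single
proximity noise term lumps together airtime variation, interrupt latency
and timer granularity at reception.

## Fleet simulator

The wake schedule is strictly periodic (every full five UTC minutes by
default; hourly in the two-tag stationary setup), so the simulator
advances window by window instead of through a generic event queue.
Devices open their windows when their *own* clocks read the scheduled
second; contact therefore depends on pairwise window overlap — a device
displaced by more than the window length relative to every partner
exchanges nothing that event (the runaway failure mode), while a fleet
that drifts from UTC *together* keeps exchanging indefinitely.  Gateways
are fixed, continuously listening receivers; they sniff
every in-range transmitter and stamp arrivals on their own ±10 ppm
clocks.

Location is a two-state INSIDE/OUTSIDE chain per device (defaults
p_exit = 0.02, p_enter = 0.10 per 5-min window — placeholders, clearly
not fitted to real animal movement).  Tags that saw a gateway during the
window are inside and do not power their GPS; outside tags attempt a fix
with probability 0.9 (0 inside), Bernoulli per attempt — the real system
reports fix failure only qualitatively.  The contact model is
configurable; the default is all-hear-all among inside tags.

One master seed drives everything; per-device and per-gateway streams
are derived by stable hashing (CRC-32) of the identifier, so event logs
are byte-for-byte reproducible and insensitive to iteration order.

Energy: each RTC set costs 6.5 µWh, a WiFi sync 412.5 µWh (inclusive of
its RTC set, hence not double-counted), and keeping time draws 720 nW.

What the simulator does **not** capture: RF propagation and
signal-strength-vs-distance, message collisions, real GPS ephemeris and
sky-view geometry, temperature-correlated drift between co-located tags
(device rates are drawn independently), battery chemistry, and real
animal movement statistics.  Passing tests therefore demonstrate the
correctness of the synchronisation logic and the self-consistency of the
error model under the stated noise — not field performance.

## Gateway evaluation

Per message the sender's window start in the gateway frame is
`arrival_stamp − rel`; per tag per event the median over its messages
(our aggregation choice again).  Airtime is *not* subtracted here — it
is common to all tags heard by one gateway and cancels in the pairwise
differences, which are the only quantities used (gateways cannot provide
UTC ground truth).  Gateway drift perturbs a pairwise difference only by
rate × window ≈ 10⁻⁵ ms at 10 ppm, asserted numerically.  Summaries are
median and raw MAD (no 1.4826 factor).

The guaranteed-error table is additive: cell = offset quantile + rated
drift over a full resynchronisation interval, rounded half away from
zero.  The underlying combined GPS+WiFi offset sample is not available,
so base quantiles are configuration inputs, by default back-solved from
the published 10-minute rows (cell − drift over 600 s).  This
reconstruction reproduces the published 60-min 95% cell of the wide
range (66 ms) and the 24-h 75%/95% cells of the narrow range (147 and
185 ms) exactly; cells that land exactly on a rounding tie (e.g.
26.1 + 5.4 = 31.5) can differ by 1 ms from print because the printed
10-minute row itself carries only integer precision.

`fit_ppm` is an ordinary least-squares slope ×10⁶ on an
(t, error) trace; because drift is only locally linear the estimator is
meant to be applied per window, and the symmetric two-segment test shows
why a whole-trace fit degenerates toward zero.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use scaled-down scenarios
chosen to exercise every code path at comfortable runtimes: a full
16-day two-tag hourly experiment (384 windows), and a 20-tag, 2-gateway,
2-day cave deployment (576 windows, ~150k pairwise comparisons).  The
two-tag run uses 2 and −1 ppm (3 ppm relative, the RTC envelope); at that
relative rate the 50 ms threshold is crossed every ≈ 4.6 h, so the first
auto-resync lands on the first hourly exchange after 16,667 s and the
relative error stays below threshold + 10.8 ms drift-per-hour + a noise
envelope.  Clock inversion (true time of a local reading) uses six
fixed-point iterations, converging to machine precision because rates
are O(10⁻⁶).  Exactness tests disable noise, millisecond rounding and
MCU drift, under which every measured deviation equals the true relative
clock error to the second-order (rate × error) term, ~10⁻⁵ ms.
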