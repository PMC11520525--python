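"""Clock-error model for animal-borne bio-loggers.

A tag measures time t' that deviates from reference (UTC) time t as

    t'(t) = t + T_error(t) = t + T_drift(t) + T_off(t)

where ``T_off`` is the offset left behind by the last synchronisation
(identical in expectation across tags with the same hardware/firmware) and
``T_drift`` is the oscillator drift accumulated since, which differs between
individual devices and varies with ambient temperature.  Drift rates are
specified in parts per million (ppm): a clock running at +1 ppm gains
86.4 ms per day.

This module provides:

* :class:`ClockSpec` / :class:`TemperatureProfile` — static clock and
  environment descriptions;
* :class:`SimulatedClock` — the t -> t' mapping with piecewise-constant
  drift rate, offset state and set-time semantics (wait until the next full
  UTC second, milliseconds reset to zero, a fixed bus-transfer latency);
* analytic drift budgets (:func:`drift_budget`, :func:`drift_budget_table`)
  giving the worst-case ``T_drift`` per day/week/month for a clock class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import pandas as pd

from .records import SyncMethod, SyncRecord

__all__ = [
    "DAY_S",
    "WEEK_S",
    "MONTH_S",
    "ClockSpec",
    "TemperatureProfile",
    "SimulatedClock",
    "TimeErrorDecomposition",
    "drift_budget",
    "drift_budget_table",
    "rtc_set_latency_s",
    "round_half_away",
    "OSCILLATOR_EXAMPLES",
]

DAY_S = 86_400
WEEK_S = 604_800
#: one month is taken as 31 days, the convention under which the published
#: per-month worst-case drifts are internally consistent
#: (e.g. 20 ppm -> 0.00002 * 86400 * 31 = 53.568 ks).
MONTH_S = 31 * DAY_S

#: RTC set command: 9 bytes over I2C at 400 kbit/s.
RTC_SET_COMMAND_BYTES = 9
I2C_BIT_RATE_HZ = 400_000


def rtc_set_latency_s(
    n_bytes: int = RTC_SET_COMMAND_BYTES, bit_rate_hz: float = I2C_BIT_RATE_HZ
) -> float:
    """Transfer time of the RTC set command, from first principles.

    9 bytes x 8 bits / 400,000 bit/s = 0.18 ms.  This is the residual
    timing error added by every clock set.
    """
    if n_bytes < 0 or bit_rate_hz <= 0:
        raise ValueError("need n_bytes >= 0 and bit_rate_hz > 0")
    return n_bytes * 8 / bit_rate_hz


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (the convention that reproduces
    every printed worst-case drift table cell, e.g. 0.2592 -> 0.26)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClockSpec:
    """Static specification of a clock component.

    Defaults describe a temperature-compensated RTC of the class used on
    current tags: +/-3 ppm maximum drift between -40 and 85 degC, 10 ms
    read resolution, and a 0.18 ms set latency (9-byte command at 400 kbit/s).
    """

    max_drift_ppm: float = 3.0
    temp_range: tuple[float, float] = (-40.0, 85.0)
    resolution_s: float = 0.01
    set_latency_s: float = rtc_set_latency_s()

    def __post_init__(self) -> None:
        if self.max_drift_ppm < 0:
            raise ValueError("max_drift_ppm must be >= 0")
        if self.resolution_s <= 0:
            raise ValueError("resolution_s must be > 0")
        if not self.temp_range[0] < self.temp_range[1]:
            raise ValueError("temp_range must satisfy min < max")


@dataclass(frozen=True)
class TemperatureProfile:
    """Piecewise-constant ambient temperature over the simulation horizon.

    ``segments`` is a sequence of ``(start_s, end_s, temp_C)`` tuples that
    must be contiguous, non-overlapping and ordered.
    """

    segments: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("profile needs at least one segment")
        prev_end = None
        for start, end, _temp in self.segments:
            if end <= start:
                raise ValueError("segment end must exceed start")
            if prev_end is not None and not math.isclose(start, prev_end):
                raise ValueError("segments must be contiguous")
            prev_end = end

    @property
    def start_s(self) -> float:
        return self.segments[0][0]

    @property
    def end_s(self) -> float:
        return self.segments[-1][1]

    def temperature_at(self, t: float) -> float:
        for start, end, temp in self.segments:
            if start <= t < end:
                return temp
        if math.isclose(t, self.end_s):
            return self.segments[-1][2]
        raise ValueError(f"t={t} outside profile [{self.start_s}, {self.end_s}]")

    def ppm_segments(
        self, temp_to_ppm: Callable[[float], float]
    ) -> tuple[tuple[float, float, float], ...]:
        """Map the temperature segments through a device-specific temp->ppm
        curve, yielding ``(start_s, end_s, ppm)`` drift-rate segments."""
        return tuple((s, e, temp_to_ppm(temp)) for s, e, temp in self.segments)


@dataclass(frozen=True)
class TimeErrorDecomposition:
    """Snapshot of the error model at one reference instant."""

    t_s: float
    t_prime_s: float
    T_drift_s: float
    T_off_s: float
    T_error_s: float

    def to_dict(self) -> dict:
        return {
            "t_s": self.t_s,
            "t_prime_s": self.t_prime_s,
            "T_drift_s": self.T_drift_s,
            "T_off_s": self.T_off_s,
            "T_error_s": self.T_error_s,
        }


@dataclass
class SimulatedClock:
    """A device clock: reference time plus drift plus synchronisation offset.

    Parameters
    ----------
    device_id
        Identifier used in logs and for deterministic tie-breaking.
    spec
        Static component specification.
    ppm_segments
        Piecewise-constant signed drift rate ``(start_s, end_s, ppm)``;
        typically derived from a :class:`TemperatureProfile` through a
        device-specific temp->ppm curve.  The edge values extend beyond the
        first/last segment so the clock is total on ``t >= epoch_s``.
    T_off_s
        Current synchronisation offset (seconds).
    anchor_t_s
        Reference time at which drift accumulation (re)started — the epoch
        or the instant of the last clock set.
    epoch_s
        Simulation epoch; reads before it are a domain error.
    """

    device_id: str
    spec: ClockSpec = field(default_factory=ClockSpec)
    ppm_segments: tuple[tuple[float, float, float], ...] = ((0.0, math.inf, 0.0),)
    T_off_s: float = 0.0
    anchor_t_s: float = 0.0
    epoch_s: float = 0.0

    def __post_init__(self) -> None:
        self.ppm_segments = tuple(self.ppm_segments)
        for start, end, ppm in self.ppm_segments:
            if end <= start:
                raise ValueError("ppm segment end must exceed start")
            if abs(ppm) > self.spec.max_drift_ppm + 1e-12:
                raise ValueError(
                    f"|ppm|={abs(ppm)} exceeds spec maximum {self.spec.max_drift_ppm}"
                )

    # -- constructors ------------------------------------------------------

    @classmethod
    def constant(
        cls,
        device_id: str,
        ppm: float,
        *,
        spec: ClockSpec | None = None,
        T_off_s: float = 0.0,
        anchor_t_s: float = 0.0,
    ) -> "SimulatedClock":
        """Clock with a single constant drift rate."""
        if spec is None:
            spec = ClockSpec(max_drift_ppm=max(abs(ppm), ClockSpec().max_drift_ppm))
        return cls(
            device_id=device_id,
            spec=spec,
            ppm_segments=((0.0, math.inf, ppm),),
            T_off_s=T_off_s,
            anchor_t_s=anchor_t_s,
        )

    @classmethod
    def from_temperature_profile(
        cls,
        device_id: str,
        profile: TemperatureProfile,
        temp_to_ppm: Callable[[float], float],
        *,
        spec: ClockSpec | None = None,
        T_off_s: float = 0.0,
    ) -> "SimulatedClock":
        spec = spec or ClockSpec()
        return cls(
            device_id=device_id,
            spec=spec,
            ppm_segments=profile.ppm_segments(temp_to_ppm),
            T_off_s=T_off_s,
            anchor_t_s=profile.start_s,
            epoch_s=profile.start_s,
        )

    # -- drift -------------------------------------------------------------

    def ppm_at(self, t: float) -> float:
        segs = self.ppm_segments
        if t < segs[0][0]:
            return segs[0][2]
        for start, end, ppm in segs:
            if start <= t < end:
                return ppm
        return segs[-1][2]

    def drift_integral(self, t0: float, t1: float) -> float:
        """Accumulated drift over ``[t0, t1]``: sum over segments of
        ppm x 1e-6 x overlap.  Exact for piecewise-constant rates."""
        if t1 < t0:
            raise ValueError("drift_integral requires t0 <= t1")
        total = 0.0
        segs = self.ppm_segments
        # clamp: extend edge rates outside the covered range
        first_start = segs[0][0]
        last_end = segs[-1][1]
        if t0 < first_start:
            total += segs[0][2] * 1e-6 * (min(t1, first_start) - t0)
        if t1 > last_end:
            total += segs[-1][2] * 1e-6 * (t1 - max(t0, last_end))
        for start, end, ppm in segs:
            lo = max(t0, start)
            hi = min(t1, end)
            if hi > lo:
                total += ppm * 1e-6 * (hi - lo)
        return total

    # -- reads -------------------------------------------------------------

    def _signed_drift_from_anchor(self, t: float) -> float:
        """Drift accumulated between the anchor and ``t``; negative when
        reading just before the anchor (e.g. the instant before a set)."""
        if t >= self.anchor_t_s:
            return self.drift_integral(self.anchor_t_s, t)
        return -self.drift_integral(t, self.anchor_t_s)

    def local_time(self, t: float) -> float:
        """Continuous local time t'(t) = t + T_drift(t) + T_off."""
        if t < self.epoch_s:
            raise ValueError(f"t={t} precedes simulation epoch {self.epoch_s}")
        return t + self._signed_drift_from_anchor(t) + self.T_off_s

    def read_rtc(self, t: float) -> float:
        """Quantised read: the RTC reports local time floored to its
        resolution (10 ms by default)."""
        res = self.spec.resolution_s
        return math.floor(self.local_time(t) / res) * res

    def true_time_of_local(self, local_s: float) -> float:
        """Invert the clock map: the reference time at which the device's
        continuous local time reads ``local_s``.

        Fixed-point iteration; converges to machine precision in a few
        rounds because drift rates are O(1e-6).
        """
        t = local_s - self.T_off_s
        for _ in range(6):
            t = local_s - self.T_off_s - self._signed_drift_from_anchor(t)
        return t

    def decompose_error(self, t: float) -> TimeErrorDecomposition:
        """Split t'(t) - t into its drift and offset terms."""
        drift = self._signed_drift_from_anchor(t)
        return TimeErrorDecomposition(
            t_s=t,
            t_prime_s=self.local_time(t),
            T_drift_s=drift,
            T_off_s=self.T_off_s,
            T_error_s=drift + self.T_off_s,
        )

    # -- set-time semantics ------------------------------------------------

    def set_clock(
        self,
        utc_target_s: float,
        at_reference_time_s: float,
        *,
        method: SyncMethod = SyncMethod.GPS,
    ) -> SyncRecord:
        """Set the RTC to a newly received UTC estimate.

        ``utc_target_s`` is the device's estimate of the current UTC at
        reference instant ``at_reference_time_s`` (the estimate error is
        whatever offset the synchronisation method left in it).  Firmware
        semantics: wait with a high-accuracy timer until the next full UTC
        second of the estimated timeline, then issue the set command, which
        zeroes the milliseconds field and costs one bus transfer
        (``spec.set_latency_s``).  The drift anchor restarts at the set.

        Post-set offset is exactly ``(estimate error) + set latency``; with
        a perfect estimate that is the 0.18 ms command-transfer time.
        """
        fire_target = math.ceil(utc_target_s - 1e-9)  # next full UTC second
        wait_s = fire_target - utc_target_s
        t_fire = at_reference_time_s + wait_s
        old_local = self.local_time(max(t_fire, self.epoch_s))
        estimate_error_s = utc_target_s - at_reference_time_s
        new_T_off = estimate_error_s + self.spec.set_latency_s
        self.T_off_s = new_T_off
        self.anchor_t_s = t_fire
        new_local = self.local_time(max(t_fire, self.epoch_s))
        return SyncRecord(
            device_id=self.device_id,
            method=method,
            reference_time_s=t_fire,
            measured_deviation_ms=(old_local - new_local) * 1e3,
            applied=True,
            post_sync_T_off_ms=new_T_off * 1e3,
        )

    def copy(self) -> "SimulatedClock":
        return replace(self)


def drift_budget(ppm: float, duration_s: float) -> float:
    """Worst-case accumulated drift (seconds) of a clock rated at ``ppm``
    over ``duration_s``: ppm x 1e-6 x duration.  Linear and monotone in
    both arguments; a hard bound for any trajectory with \\|rate\\| <= ppm."""
    if ppm < 0 or duration_s < 0:
        raise ValueError("drift_budget requires ppm >= 0 and duration_s >= 0")
    return ppm * 1e-6 * duration_s


#: Example oscillator classes used in the published worst-case drift table:
#: (label, rated max ppm, printed decimals for the day/week/month columns).
OSCILLATOR_EXAMPLES: tuple[tuple[str, float, tuple[int, int, int]], ...] = (
    ("OCXO module, 0-50 degC (Abracon AOCJY)", 0.005, (4, 4, 4)),
    ("TCXO module, 0-50 degC (Micro Crystal RV-8803-C7)", 1.5, (2, 1, 1)),
    ("TCXO module, -40-85 degC (Micro Crystal RV-8803-C7)", 3.0, (2, 1, 1)),
    ("80 MHz MCU oscillator, 25 degC (Espressif ESP32)", 10.0, (2, 1, 1)),
    ("XO module, 0-50 degC (Micro Crystal RV-3028-C7)", 20.0, (2, 1, 1)),
    ("Internal MCU oscillator, 25 degC (Microchip ATmega328P)", 20_000.0, (0, 0, 0)),
    ("Internal MCU oscillator, -40-125 degC (Microchip ATmega328P)", 140_000.0, (0, 0, 0)),
)


def drift_budget_table(
    rows: Sequence[tuple[str, float, tuple[int, int, int]]] = OSCILLATOR_EXAMPLES,
) -> pd.DataFrame:
    """Worst-case drift per day/week/month for a set of clock classes,
    rounded half-away-from-zero to each row's display precision.

    Returns a frame with columns ``component_label, ppm, per_day_s,
    per_week_s, per_month_s``.
    """
    out = []
    for label, ppm, decimals in rows:
        d_day, d_week, d_month = decimals
        out.append(
            {
                "component_label": label,
                "ppm": ppm,
                "per_day_s": round_half_away(drift_budget(ppm, DAY_S), d_day),
                "per_week_s": round_half_away(drift_budget(ppm, WEEK_S), d_week),
                "per_month_s": round_half_away(drift_budget(ppm, MONTH_S), d_month),
            }
        )
    return pd.DataFrame(out)
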