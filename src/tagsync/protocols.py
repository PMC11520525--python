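"""Pure protocol logic of the three onboard (re)synchronisation methods.

Method A — GPS: the module's reported time lags true time by a processing
and transport delay that correlates with the number of visible satellites;
a linear compensation model is added onboard.

Method B — WiFi/NTP: a single four-timestamp exchange; the offset estimate
assumes symmetric outbound/return delays, so its error is exactly half the
delay asymmetry.

Method C — proximity messages: awake tags broadcast 8 messages in an
800 ms window (one every 100 ms), each carrying a relative millisecond
timestamp within the window, the sender's UTC second and its last-sync
stamp.  Receivers map their own reception timestamp back to send time by
subtracting the estimated airtime (5.2 ms) and compare against the
sender's relative timestamp; if any deviation in the group exceeds 50 ms,
everyone adopts the clock of the most recently resynchronised participant
(gossip propagation of the collectively trusted time).

Everything here is side-effect free; the fleet simulator owns clock state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .records import ProximityMessage, SyncMethod, SyncRecord

__all__ = [
    "WINDOW_MS",
    "MESSAGE_SPACING_MS",
    "MESSAGES_PER_WINDOW",
    "AIRTIME_MS",
    "RESYNC_THRESHOLD_MS",
    "GpsDelayModel",
    "NtpExchange",
    "MalformedExchangeError",
    "NoFixError",
    "OffsetNoiseModel",
    "WindowParticipant",
    "ResyncAction",
    "ntp_offset",
    "gps_compensated_time",
    "build_window_messages",
    "adjust_received_rel",
    "proximity_deviation",
    "aggregate_window_deviations",
    "resync_decide",
    "sample_offset",
    "default_noise_models",
    "ProximityMessage",
    "SyncMethod",
    "SyncRecord",
]

WINDOW_MS = 800.0
MESSAGE_SPACING_MS = 100.0
MESSAGES_PER_WINDOW = 8
AIRTIME_MS = 5.2
RESYNC_THRESHOLD_MS = 50.0


class MalformedExchangeError(ValueError):
    """NTP exchange whose implied round-trip delay is negative."""


class NoFixError(RuntimeError):
    """GPS time requested without an acquired fix."""


# ---------------------------------------------------------------------------
# Method B: NTP over WiFi
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NtpExchange:
    """Four-timestamp NTP exchange (all in ms).

    ``t1``/``t4`` are client send/receive on the client clock; ``t2``/``t3``
    are server receive/send on the server clock.
    """

    t1: float
    t2: float
    t3: float
    t4: float

    def __post_init__(self) -> None:
        if self.t4 < self.t1:
            raise ValueError("t4 < t1: client received before it sent")
        if self.t3 < self.t2:
            raise ValueError("t3 < t2: server sent before it received")


def ntp_offset(x: NtpExchange) -> tuple[float, float]:
    """Symmetric-delay offset estimate and round-trip delay.

    offset = ((t2 - t1) + (t3 - t4)) / 2
    delay  = (t4 - t1) - (t3 - t2)

    The estimate is exact when outbound and return path delays are equal;
    otherwise it errs by half the asymmetry (outbound minus return, halved).
    """
    offset = ((x.t2 - x.t1) + (x.t3 - x.t4)) / 2.0
    delay = (x.t4 - x.t1) - (x.t3 - x.t2)
    if delay < 0:
        raise MalformedExchangeError(f"negative round-trip delay {delay} ms")
    return offset, delay


# ---------------------------------------------------------------------------
# Method A: GPS with delay compensation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GpsDelayModel:
    """Linear model of the GPS module's reporting delay (ms):
    delay(n_sats) = c0 + c1 * n_sats.

    Coefficients are firmware-calibration inputs; the defaults are the
    identity (no compensation).
    """

    c0_ms: float = 0.0
    c1_ms_per_sat: float = 0.0

    def delay_ms(self, n_sats: int) -> float:
        if n_sats < 1:
            raise ValueError("delay model requires n_sats >= 1")
        return self.c0_ms + self.c1_ms_per_sat * n_sats


def gps_compensated_time(
    reported_utc_ms: float,
    n_sats: int,
    model: GpsDelayModel,
    *,
    has_fix: bool = True,
) -> float:
    """Compensate the GPS-reported UTC for the module's processing delay.

    The reported time lags real time by the delay, so the compensation is
    *added*.  Requires an acquired fix (time is only reliably updated after
    one) and at least one visible satellite.
    """
    if not has_fix:
        raise NoFixError("GPS time is only valid after a fix is acquired")
    if n_sats < 1:
        raise ValueError("need at least one visible satellite")
    return reported_utc_ms + model.delay_ms(n_sats)


# ---------------------------------------------------------------------------
# Method C: proximity messages
# ---------------------------------------------------------------------------


@dataclass
class WindowParticipant:
    """A device's view of one transmit/receive window.

    ``utc_at_window_start_s`` is the onboard UTC second at which the device
    believes the window started (the scheduled second).
    ``true_window_start_s`` is the reference time at which the device's
    window actually began (its clock error displaces it).
    ``mcu_ppm`` is the drift rate of the main oscillator used for the
    relative millisecond timer inside the window.
    """

    device_id: str
    utc_at_window_start_s: int
    last_sync_utc_s: float
    true_window_start_s: float
    mcu_ppm: float = 0.0

    def rel_ms_at(self, t_reference_s: float) -> float:
        """The device's relative window timer reading at a reference time."""
        elapsed = t_reference_s - self.true_window_start_s
        return elapsed * (1.0 + self.mcu_ppm * 1e-6) * 1e3


def build_window_messages(
    participant: WindowParticipant,
    window_start_utc_s: int | None = None,
    *,
    n_messages: int = MESSAGES_PER_WINDOW,
    spacing_ms: float = MESSAGE_SPACING_MS,
    round_rel: bool = False,
) -> list[tuple[float, ProximityMessage]]:
    """The 8 proximity broadcasts of one window.

    Message k goes on air at reference time ``true_window_start + k * 100 ms``
    and carries the sender's own (drifting) measurement of that elapsed
    time as ``rel_ms``; with ``round_rel`` the stamp is rounded to whole
    milliseconds as transmitted on the wire.

    Returns ``(true_send_time_s, message)`` pairs.
    """
    if window_start_utc_s is None:
        window_start_utc_s = participant.utc_at_window_start_s
    out = []
    for k in range(n_messages):
        t_send = participant.true_window_start_s + k * spacing_ms / 1e3
        rel = k * spacing_ms * (1.0 + participant.mcu_ppm * 1e-6)
        if round_rel:
            rel = float(round(rel))
        out.append(
            (
                t_send,
                ProximityMessage(
                    sender_id=participant.device_id,
                    rel_ms=rel,
                    utc_s=int(window_start_utc_s),
                    last_sync_utc_s=participant.last_sync_utc_s,
                ),
            )
        )
    return out


def adjust_received_rel(rx_rel_ms: float, airtime_ms: float = AIRTIME_MS) -> float:
    """Map a reception-side relative timestamp back to send time by
    subtracting the estimated airtime."""
    return rx_rel_ms - airtime_ms


def proximity_deviation(
    receiver: WindowParticipant,
    msg: ProximityMessage,
    own_rel_ms_at_reception: float,
    *,
    airtime_ms: float = AIRTIME_MS,
    window_ms: float = WINDOW_MS,
    guard_ms: float = MESSAGE_SPACING_MS,
) -> float | None:
    """Signed clock deviation (ms) of the receiver relative to the sender.

    The receiver's reception timestamp, corrected back to send time by the
    estimated airtime, is compared with the sender's transmitted relative
    timestamp; whole-second disagreements are carried by the UTC-second
    fields:

        deviation = 1000 * (own_window_utc_s - msg.utc_s)
                    + (own_rel_at_reception - airtime) - msg.rel_ms

    Positive means the receiver's clock is ahead.  A message arriving
    outside the receiver's window (plus a one-spacing guard) is ignored
    with a warning and ``None`` is returned.
    """
    if not -guard_ms <= own_rel_ms_at_reception <= window_ms + guard_ms:
        warnings.warn(
            f"message from {msg.sender_id} outside {receiver.device_id}'s "
            f"window (own rel {own_rel_ms_at_reception:.1f} ms); ignored",
            stacklevel=2,
        )
        return None
    whole_seconds = 1000.0 * (receiver.utc_at_window_start_s - msg.utc_s)
    return whole_seconds + adjust_received_rel(own_rel_ms_at_reception, airtime_ms) - msg.rel_ms


def aggregate_window_deviations(
    per_message: Iterable[tuple[str, str, float]],
) -> dict[tuple[str, str], float]:
    """Median per (receiver, sender) of per-message deviations — robust to
    a corrupted message among the <=8 of a window."""
    buckets: dict[tuple[str, str], list[float]] = {}
    for rx, tx, dev in per_message:
        buckets.setdefault((rx, tx), []).append(dev)
    return {k: float(np.median(v)) for k, v in buckets.items()}


@dataclass(frozen=True)
class ResyncAction:
    """Outcome of a collective resynchronisation decision for one device."""

    device_id: str
    action: str  # "reference" | "adopt"
    reference_id: str
    reference_last_sync_utc_s: float
    deviation_to_reference_ms: float  # 0 for the reference itself


def _deviation_to_reference(
    device_id: str,
    reference_id: str,
    deviations: Mapping[tuple[str, str], float],
) -> float | None:
    """Signed deviation of ``device_id`` relative to the reference, chaining
    measured pairwise deviations through the exchange graph if the pair has
    no direct measurement (deviations are additive along a path)."""
    # symmetrise: dev(a,b) = -dev(b,a)
    graph: dict[str, dict[str, float]] = {}
    for (rx, tx), d in deviations.items():
        graph.setdefault(rx, {})[tx] = d
        graph.setdefault(tx, {}).setdefault(rx, -d)
    if device_id == reference_id:
        return 0.0
    # BFS accumulating signed deviation relative to the reference
    seen = {reference_id: 0.0}
    frontier = [reference_id]
    while frontier:
        nxt = []
        for node in frontier:
            for nbr, d in sorted(graph.get(node, {}).items()):
                if nbr not in seen:
                    # dev(nbr, node) = d_nbr_node; dev(nbr, ref) = dev(nbr,node)+dev(node,ref)
                    seen[nbr] = graph[nbr][node] + seen[node]
                    nxt.append(nbr)
        frontier = nxt
    return seen.get(device_id)


def resync_decide(
    participants: Sequence[WindowParticipant],
    deviations: Mapping[tuple[str, str], float],
    *,
    threshold_ms: float = RESYNC_THRESHOLD_MS,
) -> list[ResyncAction]:
    """Collective resynchronisation decision for one window.

    If any measured deviation strictly exceeds ``threshold_ms`` in
    magnitude, the participant with the most recent last-sync stamp (ties
    broken by lowest device id) becomes the reference and every other
    participant adopts its clock and its last-sync stamp.  Otherwise no
    action.  The reference's own clock is never changed.
    """
    if not participants:
        raise ValueError("resync_decide requires at least one participant")
    if not deviations or len(participants) < 2:
        return []
    max_abs = max(abs(d) for d in deviations.values())
    if not max_abs > threshold_ms:  # strictly greater than
        return []
    reference = min(participants, key=lambda p: (-p.last_sync_utc_s, p.device_id))
    actions = [
        ResyncAction(
            device_id=reference.device_id,
            action="reference",
            reference_id=reference.device_id,
            reference_last_sync_utc_s=reference.last_sync_utc_s,
            deviation_to_reference_ms=0.0,
        )
    ]
    for p in sorted(participants, key=lambda p: p.device_id):
        if p.device_id == reference.device_id:
            continue
        dev = _deviation_to_reference(p.device_id, reference.device_id, deviations)
        if dev is None:
            # not connected to the reference through this window's exchanges
            continue
        actions.append(
            ResyncAction(
                device_id=p.device_id,
                action="adopt",
                reference_id=reference.device_id,
                reference_last_sync_utc_s=reference.last_sync_utc_s,
                deviation_to_reference_ms=dev,
            )
        )
    return actions


# ---------------------------------------------------------------------------
# Offset noise models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OffsetNoiseModel:
    """Distribution of the offset a synchronisation method leaves behind,
    parameterised by the reported median and (unscaled) MAD.

    The default family is Laplace with location = median and scale =
    MAD / ln 2, under which the population MAD equals the reported MAD.
    """

    method: SyncMethod
    median_ms: float
    mad_ms: float
    family: str = "laplace"

    def __post_init__(self) -> None:
        if self.mad_ms < 0:
            raise ValueError("mad_ms must be >= 0")
        if self.family not in ("laplace", "normal"):
            raise ValueError(f"unknown noise family {self.family!r}")


def sample_offset(model: OffsetNoiseModel, rng: np.random.Generator) -> float:
    """One offset draw (ms) from the method's noise model."""
    if model.mad_ms == 0:
        return model.median_ms
    if model.family == "laplace":
        return float(rng.laplace(model.median_ms, model.mad_ms / math.log(2)))
    # normal: MAD = sigma * Phi^-1(0.75) with Phi^-1(0.75) ~ 0.67449
    return float(rng.normal(model.median_ms, model.mad_ms / 0.6744897501960817))


def default_noise_models() -> dict[SyncMethod, OffsetNoiseModel]:
    """Per-method noise defaults taken from measured stationary accuracies:
    GPS median 2.72 ms (MAD 12.47), WiFi/NTP 0.43 ms (MAD 1.51), proximity
    resynchronisation 5 ms (MAD 2)."""
    return {
        SyncMethod.GPS: OffsetNoiseModel(SyncMethod.GPS, 2.72, 12.47),
        SyncMethod.WIFI_NTP: OffsetNoiseModel(SyncMethod.WIFI_NTP, 0.43, 1.51),
        SyncMethod.PROXIMITY: OffsetNoiseModel(SyncMethod.PROXIMITY, 5.0, 2.0),
    }
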