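"""Shared record types exchanged between the protocol, simulator and
evaluation layers.

These are deliberately plain dataclasses: every record must serialise to a
JSON-lines event log and back without loss, and byte-identical logs for
identical (config, seed) pairs are part of the simulator contract.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from enum import Enum


class SyncMethod(str, Enum):
    """Which synchronisation path produced a time fix."""

    GPS = "GPS"
    WIFI_NTP = "WIFI_NTP"
    PROXIMITY = "PROXIMITY"


@dataclass(frozen=True)
class ProximityMessage:
    """Payload of one wireless proximity broadcast.

    Parameters
    ----------
    sender_id
        Identifier of the transmitting tag.
    rel_ms
        Milliseconds since the sender's transmit/receive window started,
        as measured by the sender's own (drifting) main oscillator.
        Always within ``[0, 800]``.
    utc_s
        The sender's onboard UTC estimate at second resolution when its
        window started.
    last_sync_utc_s
        UTC second of the sender's most recent (re)synchronisation; the
        gossip protocol propagates the largest such stamp through a group.
    """

    sender_id: str
    rel_ms: float
    utc_s: int
    last_sync_utc_s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rel_ms <= 800.0 + 1e-9:
            raise ValueError(
                f"rel_ms={self.rel_ms} outside the 800 ms transmit/receive window"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SyncRecord:
    """One applied (or measured-only) synchronisation event."""

    device_id: str
    method: SyncMethod
    reference_time_s: float
    measured_deviation_ms: float
    applied: bool
    post_sync_T_off_ms: float

    def to_dict(self) -> dict:
        d = asdict(self)
        d["method"] = self.method.value
        return d


@dataclass(frozen=True)
class GatewaySniffRecord:
    """A proximity message overheard by a fixed gateway.

    The arrival is stamped on the gateway's *own* relative clock
    (``gw_rel_arrival_ms``); gateways are not UTC ground truth.  ``event_id``
    identifies the scheduled transmit/receive window the message belongs to.
    """

    gateway_id: str
    event_id: int
    gw_rel_arrival_ms: float
    message: ProximityMessage

    def to_dict(self) -> dict:
        d = asdict(self)
        d["message"] = self.message.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GatewaySniffRecord":
        return cls(
            gateway_id=d["gateway_id"],
            event_id=int(d["event_id"]),
            gw_rel_arrival_ms=float(d["gw_rel_arrival_ms"]),
            message=ProximityMessage(**d["message"]),
        )
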