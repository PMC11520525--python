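"""5-byte compressed UTC timestamp used to annotate sensor data.

Layout: 4 bytes of UNIX seconds (big-endian, unsigned) followed by 1 byte
of milliseconds at 10 ms resolution (0..99).  Big-endian keeps
byte-lexicographic order equal to chronological order.  Sub-resolution
milliseconds are truncated (floor), matching the semantics of an RTC
counter: the stored stamp never claims more elapsed time than has passed.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CompressedTimestamp",
    "encode_timestamp",
    "decode_timestamp",
    "rtc_quantize_ms",
    "TimestampEncodeError",
    "TimestampFormatError",
]

RECORD_BYTES = 5
_MAX_SECONDS = 2**32


class TimestampEncodeError(ValueError):
    """Input outside the representable range of the 5-byte format."""


class TimestampFormatError(ValueError):
    """Malformed 5-byte blob."""


def rtc_quantize_ms(ms: int) -> int:
    """Quantise milliseconds to the RTC's 10 ms grid: 10 * floor(ms / 10)."""
    if not 0 <= ms <= 999:
        raise ValueError(f"ms={ms} outside [0, 999]")
    return 10 * (int(ms) // 10)


def encode_timestamp(utc_seconds: int, ms: int = 0) -> bytes:
    """Pack (UNIX seconds, milliseconds) into 5 bytes."""
    if not 0 <= utc_seconds < _MAX_SECONDS:
        raise TimestampEncodeError(f"utc_seconds={utc_seconds} outside [0, 2^32)")
    if not 0 <= ms <= 999:
        raise TimestampEncodeError(f"ms={ms} outside [0, 999]")
    return int(utc_seconds).to_bytes(4, "big") + bytes([int(ms) // 10])


def decode_timestamp(blob: bytes) -> tuple[int, int]:
    """Unpack a 5-byte blob to (UNIX seconds, milliseconds on the 10 ms
    grid).  Roundtrip: decode(encode(s, ms)) == (s, 10 * floor(ms / 10))."""
    if len(blob) != RECORD_BYTES:
        raise TimestampFormatError(f"expected {RECORD_BYTES} bytes, got {len(blob)}")
    centi_ms = blob[4]
    if centi_ms > 99:
        raise TimestampFormatError(f"milliseconds byte {centi_ms} > 99")
    return int.from_bytes(blob[:4], "big"), centi_ms * 10


@dataclass(frozen=True)
class CompressedTimestamp:
    """In-memory form of the 5-byte stamp."""

    seconds: int
    centi_ms: int  # units of 10 ms, 0..99

    def __post_init__(self) -> None:
        if not 0 <= self.seconds < _MAX_SECONDS:
            raise ValueError("seconds outside [0, 2^32)")
        if not 0 <= self.centi_ms <= 99:
            raise ValueError("centi_ms outside [0, 99]")

    @classmethod
    def from_unix(cls, utc_seconds: int, ms: int = 0) -> "CompressedTimestamp":
        return cls(int(utc_seconds), rtc_quantize_ms(ms) // 10)

    @classmethod
    def from_bytes(cls, blob: bytes) -> "CompressedTimestamp":
        seconds, ms = decode_timestamp(blob)
        return cls(seconds, ms // 10)

    def to_bytes(self) -> bytes:
        return encode_timestamp(self.seconds, self.centi_ms * 10)

    @property
    def ms(self) -> int:
        return self.centi_ms * 10

    def as_float_seconds(self) -> float:
        return self.seconds + self.centi_ms / 100.0
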