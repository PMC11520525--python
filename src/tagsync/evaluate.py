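"""Gateway-based relative-error estimation and guaranteed error budgets.

Gateways sniff proximity messages and stamp arrivals on their own relative
clocks, which are themselves drifting — so they cannot serve as UTC ground
truth, but *differences* between tags measured through the same gateway in
the same 800 ms event are valid: subtracting each message's in-window
relative timestamp from its gateway arrival stamp estimates the sender's
window start time in the gateway's frame, and pairwise differences of
those start times estimate the relative clock errors between tags.
Airtime and gateway clock offset are common to both tags of a pair and
cancel; gateway drift changes a difference only by (drift rate) x (800 ms),
about 1e-5 ms at 10 ppm.

Also here: median/MAD summaries (MAD unscaled, no normal-consistency
factor), the additive worst-case error-budget table (offset quantile plus
rated drift x resynchronisation interval), and a least-squares drift-rate
estimator for error traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clock import drift_budget, round_half_away
from .records import GatewaySniffRecord

__all__ = [
    "GatewaySniffRecord",
    "PairwiseDifference",
    "SummaryStats",
    "BudgetRow",
    "start_times",
    "event_start_times",
    "pairwise_relative_errors",
    "all_pairwise_relative_errors",
    "median_mad",
    "error_budget_table",
    "infer_base_quantiles",
    "reference_budget_inputs",
    "fit_ppm",
    "evaluate_event_log",
]

#: Quantile levels of the guaranteed-error table.
BUDGET_QUANTILE_LEVELS = (0.75, 0.85, 0.95)

#: Printed 10-minute-interval worst-case errors (ms) per quantile level for
#: the two rated temperature ranges, together with the rated RTC drift for
#: each range.  These published cells are the calibration inputs from which
#: base offset quantiles are back-solved (the underlying offset sample is
#: not published).
TABLE2_10MIN_CELLS_MS: dict[tuple[float, float], dict[float, float]] = {
    (0.0, 50.0): {0.75: 18.0, 0.85: 27.0, 0.95: 56.0},
    (-40.0, 85.0): {0.75: 19.0, 0.85: 28.0, 0.95: 57.0},
}
RATED_PPM_BY_RANGE: dict[tuple[float, float], float] = {
    (0.0, 50.0): 1.5,
    (-40.0, 85.0): 3.0,
}


@dataclass(frozen=True)
class PairwiseDifference:
    """Signed start-time difference (a minus b, ms) within one event."""

    event_id: int
    device_a: str
    device_b: str
    delta_ms: float


@dataclass(frozen=True)
class SummaryStats:
    """Median and raw (unscaled) median absolute deviation."""

    median: float
    mad: float
    n: int


@dataclass(frozen=True)
class BudgetRow:
    """One cell of the guaranteed worst-case error table."""

    temp_range: tuple[float, float]
    resync_interval_s: float
    quantile: float
    max_T_error_ms: float


# ---------------------------------------------------------------------------
# Start times and pairwise differences
# ---------------------------------------------------------------------------


def start_times(records: Sequence[GatewaySniffRecord]) -> dict[str, float]:
    """Per-tag window start time in the gateway frame, for the records of
    one (gateway, event).

    Per message: arrival stamp minus the in-window relative timestamp; per
    tag: the median over its (up to 8) messages, robust to one corrupted
    message.  Airtime is deliberately not subtracted — it is common to all
    tags heard by the gateway and cancels in pairwise differences.
    """
    if not records:
        raise ValueError("start_times requires at least one record")
    keys = {(r.gateway_id, r.event_id) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple (gateway, event) groups: {sorted(keys)}")
    per_tag: dict[str, list[float]] = {}
    for r in records:
        per_tag.setdefault(r.message.sender_id, []).append(
            r.gw_rel_arrival_ms - r.message.rel_ms
        )
    return {tag: float(np.median(v)) for tag, v in sorted(per_tag.items())}


def event_start_times(records: Iterable[GatewaySniffRecord]) -> pd.DataFrame:
    """Start-time estimates for every (gateway, event, tag) in a sniff log."""
    groups: dict[tuple[str, int], list[GatewaySniffRecord]] = {}
    for r in records:
        groups.setdefault((r.gateway_id, r.event_id), []).append(r)
    rows = []
    for (gw, ev), recs in sorted(groups.items()):
        for tag, t0 in start_times(recs).items():
            rows.append(
                {"gateway_id": gw, "event_id": ev, "sender_id": tag, "start_ms": t0}
            )
    return pd.DataFrame(rows, columns=["gateway_id", "event_id", "sender_id", "start_ms"])


def pairwise_relative_errors(
    starts: Mapping[str, float], event_id: int = 0
) -> list[PairwiseDifference]:
    """All unordered pairwise start-time differences within one event.

    Antisymmetric by construction (delta(a, b) = -delta(b, a)) and exactly
    additive along chains within the event.  Fewer than two tags yield an
    empty list.
    """
    tags = sorted(starts)
    return [
        PairwiseDifference(event_id, a, b, starts[a] - starts[b])
        for a, b in combinations(tags, 2)
    ]


def all_pairwise_relative_errors(starts_frame: pd.DataFrame) -> pd.DataFrame:
    """Pairwise differences for every (gateway, event) group of an
    :func:`event_start_times` frame."""
    rows = []
    for (gw, ev), grp in starts_frame.groupby(["gateway_id", "event_id"], sort=True):
        starts = dict(zip(grp.sender_id, grp.start_ms))
        for pd_ in pairwise_relative_errors(starts, event_id=ev):
            rows.append(
                {
                    "gateway_id": gw,
                    "event_id": ev,
                    "device_a": pd_.device_a,
                    "device_b": pd_.device_b,
                    "delta_ms": pd_.delta_ms,
                }
            )
    return pd.DataFrame(
        rows, columns=["gateway_id", "event_id", "device_a", "device_b", "delta_ms"]
    )


def median_mad(xs: Iterable[float]) -> SummaryStats:
    """Median and raw median absolute deviation (no 1.4826 scaling)."""
    arr = np.asarray(list(xs), dtype=float)
    if arr.size == 0:
        raise ValueError("median_mad requires at least one value")
    med = float(np.median(arr))
    return SummaryStats(median=med, mad=float(np.median(np.abs(arr - med))), n=int(arr.size))


# ---------------------------------------------------------------------------
# Guaranteed error budgets
# ---------------------------------------------------------------------------


def error_budget_table(
    base_offset_quantiles_ms: Mapping[float, float],
    ppm: float,
    intervals_s: Sequence[float],
    *,
    temp_range: tuple[float, float] = (-40.0, 85.0),
) -> list[BudgetRow]:
    """Worst-case permanent error per resynchronisation interval.

    A cell is the synchronisation-offset quantile plus the rated drift
    accumulated over a full interval,

        cell = round(base_q + ppm * 1e-6 * interval_s * 1000) ms,

    rounded half away from zero.  Monotone in interval, ppm and quantile
    level whenever the base quantiles are.
    """
    if ppm < 0 or any(i < 0 for i in intervals_s):
        raise ValueError("ppm and intervals must be >= 0")
    if any(q < 0 for q in base_offset_quantiles_ms.values()):
        raise ValueError("base offset quantiles must be >= 0")
    rows = []
    for interval in intervals_s:
        drift_ms = drift_budget(ppm, interval) * 1e3
        for level in sorted(base_offset_quantiles_ms):
            rows.append(
                BudgetRow(
                    temp_range=temp_range,
                    resync_interval_s=float(interval),
                    quantile=level,
                    max_T_error_ms=round_half_away(
                        base_offset_quantiles_ms[level] + drift_ms
                    ),
                )
            )
    return rows


def infer_base_quantiles(
    printed_cells_ms: Mapping[float, float], ppm: float, interval_s: float = 600.0
) -> dict[float, float]:
    """Back out base offset quantiles from a printed short-interval row by
    removing its drift term (cell - ppm * 1e-6 * interval * 1000)."""
    drift_ms = drift_budget(ppm, interval_s) * 1e3
    return {level: cell - drift_ms for level, cell in sorted(printed_cells_ms.items())}


def reference_budget_inputs() -> dict[tuple[float, float], dict[float, float]]:
    """Base offset quantiles for both rated temperature ranges, back-solved
    from the published 10-minute rows."""
    return {
        rng: infer_base_quantiles(cells, RATED_PPM_BY_RANGE[rng])
        for rng, cells in TABLE2_10MIN_CELLS_MS.items()
    }


# ---------------------------------------------------------------------------
# Drift-rate fitting
# ---------------------------------------------------------------------------


def fit_ppm(t_s: Sequence[float], error_s: Sequence[float]) -> float:
    """Least-squares drift rate (ppm) of an error trace.

    Fits a straight line to (t, T_error) and returns the slope x 1e6.
    Exact on noiseless constant-rate data.  Drift is not globally linear
    (it follows temperature), so fit windows over which the rate is
    roughly constant.
    """
    t = np.asarray(t_s, dtype=float)
    e = np.asarray(error_s, dtype=float)
    if t.size != e.size or t.size < 2:
        raise ValueError("need >= 2 (t, error) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    slope = np.polyfit(t, e, 1)[0]
    return float(slope * 1e6)


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def evaluate_event_log(log) -> tuple[pd.DataFrame, SummaryStats]:
    """Run the full gateway chain on a simulated event log: sniff records
    -> per-event start times -> pairwise differences -> |delta| summary."""
    starts = event_start_times(log.sniff_records())
    pairs = all_pairwise_relative_errors(starts)
    if pairs.empty:
        raise ValueError("no pairwise differences: log contains no multi-tag events")
    stats = median_mad(np.abs(pairs.delta_ms))
    return pairs, stats
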