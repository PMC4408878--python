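"""Bout detection: transient frequency elevations above a trailing baseline.

Decentralized stomatogastric preparations intermittently produce "bouts" —
short runs of markedly faster pyloric cycling that have been read as signs of
an ongoing network-retuning process.  The detection statistic operates on the
per-cycle frequency series: at candidate cycle *i*, the background is the
mean of the previous ``lookback`` (default 10) cycle frequencies; the rule
fires if the next ``lookahead`` (default 3) frequencies, starting at *i*, are
all at least ``1 + rel_increase`` (default 40% increase) times the
background.  Consecutive firing indices are merged into a single bout event;
a new event requires at least one non-firing index in between.  The ">= 40%"
reading of the threshold is the default; a strict ">" switch is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .longterm import PreparationTimeline

__all__ = [
    "BoutParams",
    "BoutEvent",
    "detect_bouts",
    "firing_indices",
    "count_bouts_per_day",
    "time_to_first_bout",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoutParams:
    """Trailing-mean rule parameters: 10-cycle background, 3-cycle run, +40%."""

    lookback: int = 10
    lookahead: int = 3
    rel_increase: float = 0.40
    strict: bool = False  # True: require > threshold instead of >=

    def __post_init__(self):
        if self.lookback < 1 or self.lookahead < 1:
            raise ValueError("lookback and lookahead must be >= 1")
        if self.rel_increase <= 0:
            raise ValueError("rel_increase must be > 0")


@dataclass(frozen=True)
class BoutEvent:
    """One merged bout: first firing index, its time, and the covered extent."""

    detect_index: int
    detect_time: float | None
    extent: tuple[int, int]  # (first, last) qualifying cycle index, inclusive


def firing_indices(frequencies: np.ndarray, params: BoutParams) -> np.ndarray:
    """Indices where the trailing-mean rule fires (before merging)."""
    f = np.asarray(frequencies, dtype=float)
    n = f.size
    lb, la = params.lookback, params.lookahead
    if n < lb + la:
        return np.empty(0, dtype=int)
    # background: trailing mean of the lb cycles before each candidate
    csum = np.concatenate(([0.0], np.cumsum(f)))
    cand = np.arange(lb, n - la + 1)
    background = (csum[cand] - csum[cand - lb]) / lb
    thresh = (1.0 + params.rel_increase) * background
    # all of f[i .. i+la-1] must clear the threshold for candidate i
    ok = np.ones(cand.size, dtype=bool)
    for j in range(la):
        if params.strict:
            ok &= f[cand + j] > thresh
        else:
            ok &= f[cand + j] >= thresh
    return cand[ok]


def detect_bouts(
    frequencies: np.ndarray,
    params: BoutParams = BoutParams(),
    times: np.ndarray | None = None,
) -> list[BoutEvent]:
    """Detect merged bout events in a per-cycle frequency series.

    ``times``, if given, supplies ``detect_time`` (e.g. the PD start of each
    cycle).  With fewer than ``lookback + lookahead`` cycles an empty list is
    returned with a logged notice.
    """
    f = np.asarray(frequencies, dtype=float)
    if f.size < params.lookback + params.lookahead:
        logger.info(
            "series of %d cycles shorter than lookback+lookahead=%d: no bouts",
            f.size,
            params.lookback + params.lookahead,
        )
        return []
    fire = firing_indices(f, params)
    if fire.size == 0:
        return []
    if times is not None:
        times = np.asarray(times, dtype=float)
        if times.size != f.size:
            raise ValueError("times must parallel frequencies")
    # merge runs of consecutive firing indices
    brk = np.flatnonzero(np.diff(fire) > 1)
    run_starts = np.concatenate(([0], brk + 1))
    run_ends = np.concatenate((brk, [fire.size - 1]))
    events: list[BoutEvent] = []
    for s, e in zip(run_starts, run_ends):
        first = int(fire[s])
        last = int(fire[e]) + params.lookahead - 1
        events.append(
            BoutEvent(
                detect_index=first,
                detect_time=float(times[first]) if times is not None else None,
                extent=(first, last),
            )
        )
    return events


def count_bouts_per_day(
    events: list[BoutEvent],
    timeline: PreparationTimeline,
    duration: float,
) -> np.ndarray:
    """Bin events into 24 h windows from recording start (day 1 = first 24 h)."""
    n_days = int(np.ceil(duration / 86400.0)) if duration > 0 else 0
    counts = np.zeros(max(n_days, 1), dtype=int)
    for ev in events:
        if ev.detect_time is None:
            raise ValueError("event lacks detect_time; pass cycle times to detect_bouts")
        rel = ev.detect_time - timeline.recording_start
        if rel < 0 or rel > duration:
            raise ValueError(f"event at {ev.detect_time} s outside recorded span")
        counts[min(int(rel // 86400.0), counts.size - 1)] += 1
    return counts


def time_to_first_bout(
    events: list[BoutEvent], timeline: PreparationTimeline
) -> float | None:
    """Latency from decentralization to the first subsequent bout, seconds.

    ``None`` when the preparation is not decentralized or no bout follows.
    """
    if timeline.decentralization_time is None:
        return None
    after = [
        ev.detect_time
        for ev in events
        if ev.detect_time is not None and ev.detect_time >= timeline.decentralization_time
    ]
    if not after:
        return None
    return float(min(after) - timeline.decentralization_time)
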