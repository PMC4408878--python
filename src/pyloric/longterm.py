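"""Long-duration summaries of cycle tables.

Multi-day recordings are summarised the way long-term stomatogastric datasets
are reported: median frequency in 6-min (0.1 h) bins for single-preparation
time courses, hourly box statistics across preparations, per-day (24 h) means
of frequency and phases, within- and across-preparation coefficients of
variation, the fastest 5 h stretch of post-decentralization data within the
first 120 h (a published operationalisation of "recovery"), silence
detection, short snapshot means (e.g. the 30 min post-decentralization
state), and pre/post contrasts around saline exchanges.

Day 1 starts at the decentralization time for decentralized preparations and
at the matched post-baseline time (recording start + 1 h) for intact ones.
Quartiles use linear interpolation; whiskers extend to the most extreme datum
within 1.5 interquartile ranges of the nearest quartile, points beyond are
listed as outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PreparationTimeline",
    "BinnedSeries",
    "BoxStats",
    "bin_series",
    "boxstats",
    "hourly_boxstats",
    "daily_mean",
    "snapshot_mean",
    "fastest_window",
    "within_prep_cv",
    "across_prep_cv",
    "detect_silence",
    "saline_effect",
]

logger = logging.getLogger(__name__)

HOUR = 3600.0
DAY = 86400.0


@dataclass(frozen=True)
class PreparationTimeline:
    """Condition metadata and event times of one preparation (seconds)."""

    prep_id: str
    condition: str = "decentralized"
    recording_start: float = 0.0
    decentralization_time: float | None = None
    saline_exchange_times: tuple[float, ...] = ()
    baseline_duration: float = HOUR  # intact day-1 reference offset

    def day_zero(self) -> float:
        """Time from which 24 h day bins are counted."""
        if self.decentralization_time is not None:
            return self.decentralization_time
        return self.recording_start + self.baseline_duration


@dataclass(frozen=True)
class BinnedSeries:
    """Uniform-width binned statistic of frequency; empty bins are NaN."""

    bin_width_h: float
    statistic: str
    bin_edges_h: np.ndarray
    values: np.ndarray

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class BoxStats:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = field(default_factory=tuple)
    n: int = 0


def _valid(cycles: pd.DataFrame) -> pd.DataFrame:
    return cycles[cycles["valid"].to_numpy(dtype=bool)]


def bin_series(
    cycles: pd.DataFrame, bin_width_h: float = 0.1, statistic: str = "median"
) -> BinnedSeries:
    """Per-bin frequency statistic (median or mean) by PD-start time.

    Bins of ``bin_width_h`` hours from the earliest cycle; bins with no valid
    cycle carry NaN (absent), never zero.
    """
    if bin_width_h <= 0:
        raise ValueError("bin_width_h must be > 0")
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    v = _valid(cycles)
    if len(v) == 0:
        return BinnedSeries(bin_width_h, statistic, np.empty(0), np.empty(0))
    t_h = v["pd_start"].to_numpy() / HOUR
    f = v["frequency"].to_numpy()
    idx = np.floor(t_h / bin_width_h).astype(int)
    n_bins = idx.max() + 1
    vals = np.full(n_bins, np.nan)
    ser = pd.Series(f).groupby(idx)
    agg = ser.median() if statistic == "median" else ser.mean()
    vals[agg.index.to_numpy()] = agg.to_numpy()
    edges = np.arange(n_bins + 1) * bin_width_h
    return BinnedSeries(bin_width_h, statistic, edges, vals)


def boxstats(values) -> BoxStats:
    """Box-plot statistics with linearly interpolated quartiles.

    Whiskers extend to the most extreme datum within 1.5 IQR of the nearest
    quartile; every point beyond is an outlier.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite values")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    out = x[(x < lo_fence) | (x > hi_fence)]
    return BoxStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(sorted(float(o) for o in out)),
        n=int(x.size),
    )


def hourly_boxstats(
    hourly_means: dict[str, np.ndarray] | pd.DataFrame,
) -> list[BoxStats | None]:
    """Per-hour box statistics across preparations.

    Input: per-preparation hourly mean frequencies, either a mapping
    ``{prep_id: array}`` (NaN for missing hours) or an equivalent DataFrame
    (rows = preparations).  Hours with no data yield ``None``.
    """
    if isinstance(hourly_means, dict):
        width = max(len(v) for v in hourly_means.values())
        mat = np.full((len(hourly_means), width), np.nan)
        for i, v in enumerate(hourly_means.values()):
            mat[i, : len(v)] = v
    else:
        mat = hourly_means.to_numpy(dtype=float)
    out: list[BoxStats | None] = []
    for h in range(mat.shape[1]):
        col = mat[:, h]
        col = col[np.isfinite(col)]
        out.append(boxstats(col) if col.size else None)
    return out


def daily_mean(
    cycles: pd.DataFrame,
    timeline: PreparationTimeline,
    n_days: int = 6,
) -> pd.DataFrame:
    """Per-day means of frequency and phases in 24 h bins from day zero.

    Day zero is the decentralization time (intact: matched post-baseline
    time).  Days with zero valid cycles are absent from the result; callers
    assembling repeated-measures tables treat missing days as exclusions.
    LP phases average only LP-active cycles.
    """
    v = _valid(cycles)
    rel = v["pd_start"].to_numpy() - timeline.day_zero()
    in_span = (rel >= 0) & (rel < n_days * DAY)
    v = v[in_span]
    if len(v) == 0:
        return pd.DataFrame(
            columns=["day", "frequency", "pd_off_phase", "lp_on_phase", "lp_off_phase", "n_cycles"]
        )
    day = (rel[in_span] // DAY).astype(int) + 1
    g = v.assign(day=day).groupby("day")
    rows = []
    for d, sub in g:
        active = sub[~sub["lp_silent"].to_numpy(dtype=bool)]
        rows.append(
            {
                "day": int(d),
                "frequency": float(sub["frequency"].mean()),
                "pd_off_phase": float(sub["pd_off_phase"].mean()),
                "lp_on_phase": float(active["lp_on_phase"].mean()) if len(active) else np.nan,
                "lp_off_phase": float(active["lp_off_phase"].mean()) if len(active) else np.nan,
                "n_cycles": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)


def snapshot_mean(
    cycles: pd.DataFrame, t0: float, halfwidth: float = 300.0
) -> float | None:
    """Mean valid-cycle frequency in ``[t0 - halfwidth, t0 + halfwidth]``.

    ``None`` (logged) when the window holds no valid cycle.
    """
    v = _valid(cycles)
    t = v["pd_start"].to_numpy()
    mask = (t >= t0 - halfwidth) & (t <= t0 + halfwidth)
    if not mask.any():
        logger.info("snapshot window around %.1f s contains no valid cycles", t0)
        return None
    return float(v["frequency"].to_numpy()[mask].mean())


def fastest_window(
    cycles: pd.DataFrame,
    timeline: PreparationTimeline,
    window_h: float = 5.0,
    horizon_h: float = 120.0,
    step_h: float = 0.1,
    min_occupancy: float = 0.5,
) -> dict | None:
    """Fastest ``window_h``-hour stretch after decentralization.

    Slides candidate windows in ``step_h`` steps over
    ``[decentralization, decentralization + horizon_h]``, maximising the mean
    valid-cycle frequency; ties break to the earliest start.  Windows in
    which fewer than ``min_occupancy`` of the ``step_h`` sub-bins contain a
    valid cycle are ineligible (prevents degenerate maxima over near-silent
    stretches).  Returns start time (s), mean frequency, mean phases and the
    cycle-to-cycle frequency CV inside the window, or ``None``.
    """
    t_dec = timeline.decentralization_time
    if t_dec is None:
        raise ValueError("fastest_window requires a decentralized preparation")
    v = _valid(cycles)
    t = v["pd_start"].to_numpy()
    f = v["frequency"].to_numpy()
    order = np.argsort(t)
    t, f = t[order], f[order]
    v = v.iloc[order]

    win = window_h * HOUR
    step = step_h * HOUR
    last_cycle = t[-1] if t.size else t_dec
    limit = min(t_dec + horizon_h * HOUR, last_cycle)
    if limit - t_dec < win:
        return None
    n_steps = int(np.floor((limit - t_dec - win) / step)) + 1
    n_sub = int(round(win / step))

    # prefix sums over cycles plus sub-bin occupancy via searchsorted
    csum = np.concatenate(([0.0], np.cumsum(f)))
    best = None
    for k in range(n_steps):
        w0 = t_dec + k * step
        w1 = w0 + win
        i0 = np.searchsorted(t, w0, side="left")
        i1 = np.searchsorted(t, w1, side="left")
        if i1 <= i0:
            continue
        sub_edges = w0 + np.arange(n_sub + 1) * step
        occ_counts = np.diff(np.searchsorted(t, sub_edges, side="left"))
        if (occ_counts > 0).sum() < min_occupancy * n_sub:
            continue
        mean_f = (csum[i1] - csum[i0]) / (i1 - i0)
        if best is None or mean_f > best[0] + 1e-15:
            best = (mean_f, w0, i0, i1)
    if best is None:
        return None
    mean_f, w0, i0, i1 = best
    sub = v.iloc[i0:i1]
    active = sub[~sub["lp_silent"].to_numpy(dtype=bool)]
    fw = sub["frequency"].to_numpy()
    return {
        "start_s": float(w0),
        "mean_frequency": float(mean_f),
        "pd_off_phase": float(sub["pd_off_phase"].mean()),
        "lp_on_phase": float(active["lp_on_phase"].mean()) if len(active) else np.nan,
        "lp_off_phase": float(active["lp_off_phase"].mean()) if len(active) else np.nan,
        "cycle_cv": float(fw.std(ddof=1) / fw.mean()) if fw.size > 1 else 0.0,
        "n_cycles": int(i1 - i0),
    }


def within_prep_cv(frequencies) -> float:
    """Cycle-to-cycle coefficient of variation: sample SD / mean."""
    f = np.asarray(frequencies, dtype=float)
    f = f[np.isfinite(f)]
    if f.size < 2:
        return 0.0
    m = f.mean()
    if m == 0:
        raise ValueError("zero mean frequency: CV undefined")
    return float(f.std(ddof=1) / m)


def across_prep_cv(per_prep_means) -> float:
    """Across-preparation CV of (daily) mean frequencies: SD / mean."""
    return within_prep_cv(per_prep_means)


def detect_silence(
    pd_burst_starts: np.ndarray,
    span: tuple[float, float],
    window: float = 60.0,
    min_bursts: int = 3,
) -> list[tuple[float, float]]:
    """Silent intervals: maximal unions of ``window``-s tiles with < ``min_bursts`` PD bursts."""
    t0, t1 = span
    if t1 <= t0:
        raise ValueError("empty span")
    t = np.asarray(pd_burst_starts, dtype=float)
    n_win = int(np.ceil((t1 - t0) / window))
    edges = t0 + np.arange(n_win + 1) * window
    counts = np.histogram(t, bins=edges)[0]
    silent = counts < min_bursts
    out: list[tuple[float, float]] = []
    i = 0
    while i < n_win:
        if silent[i]:
            j = i
            while j + 1 < n_win and silent[j + 1]:
                j += 1
            out.append((float(edges[i]), float(min(edges[j + 1], t1))))
            i = j + 1
        else:
            i += 1
    return out


def saline_effect(
    cycles: pd.DataFrame, timeline: PreparationTimeline
) -> pd.DataFrame:
    """Mean valid-cycle frequency in the 1 h before and 1 h after each exchange.

    Windows are ``[t - 1 h, t)`` and ``(t, t + 1 h]``; exchanges closer than
    2 h use truncated, non-overlapping windows (logged).  Exchanges with less
    than 30 min of data on either side are skipped (logged).
    """
    v = _valid(cycles)
    t = v["pd_start"].to_numpy()
    f = v["frequency"].to_numpy()
    ex = sorted(timeline.saline_exchange_times)
    rows = []
    for i, te in enumerate(ex):
        pre_lo = te - HOUR
        post_hi = te + HOUR
        # exchanges < 2 h apart: split the shared stretch at the midpoint so
        # the post window of one and the pre window of the next never overlap
        if i > 0 and te - ex[i - 1] < 2 * HOUR:
            pre_lo = max(pre_lo, (te + ex[i - 1]) / 2.0)
            logger.info("exchange at %.0f s: pre window truncated to %.0f s", te, te - pre_lo)
        if i + 1 < len(ex) and ex[i + 1] - te < 2 * HOUR:
            post_hi = min(post_hi, (te + ex[i + 1]) / 2.0)
            logger.info("exchange at %.0f s: post window truncated to %.0f s", te, post_hi - te)
        if te - pre_lo < 1800.0 or post_hi - te < 1800.0:
            logger.info("exchange at %.0f s skipped: < 30 min of data on one side", te)
            continue
        pre_mask = (t >= pre_lo) & (t < te)
        post_mask = (t > te) & (t <= post_hi)
        if not pre_mask.any() or not post_mask.any():
            logger.info("exchange at %.0f s skipped: empty window", te)
            continue
        rows.append(
            {
                "prep_id": timeline.prep_id,
                "exchange_time_s": float(te),
                "pre_mean": float(f[pre_mask].mean()),
                "post_mean": float(f[post_mask].mean()),
            }
        )
    return pd.DataFrame(rows, columns=["prep_id", "exchange_time_s", "pre_mean", "post_mean"])
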