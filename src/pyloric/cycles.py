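"""Per-cycle period, frequency, and PD/LP phase tables.

A pyloric cycle runs from one PD burst onset to the next; all phases are
latencies from the PD burst start divided by the cycle period, so they are
dimensionless in [0, 1) for a well-formed triphasic rhythm.  The cycle table
is the central data structure of the pipeline: one row per cycle with the
period, instantaneous frequency, the three phases (PD off, LP on, LP off),
and validity flags that downstream summaries respect.

Conventions (documented, since the original acquisition software's are not
published):

* period is PD-start-to-PD-start (onset-referenced);
* a gap longer than ``gap_factor`` (default 5) times the trailing median
  period breaks the cycle chain — no cycle spans a pause or silence; the row
  is kept but marked invalid with reason ``"gap"``;
* the LP burst of cycle *i* is the first LP burst starting in
  ``[pd_start_i, pd_start_{i+1})`` (half-open); additional LP bursts in the
  same cycle are counted in ``extra_lp`` and otherwise ignored;
* cycles with no LP burst are retained with ``lp_silent`` set; aggregate
  LP-phase statistics exclude them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = ["build_cycles", "filter_cycles", "phase_frequency_regression", "CYCLE_COLUMNS"]

CYCLE_COLUMNS = [
    "index",
    "pd_start",
    "pd_end",
    "lp_start",
    "lp_end",
    "period",
    "frequency",
    "pd_off_phase",
    "lp_on_phase",
    "lp_off_phase",
    "valid",
    "lp_silent",
    "extra_lp",
    "invalid_reason",
]


def _empty_table() -> pd.DataFrame:
    df = pd.DataFrame({c: [] for c in CYCLE_COLUMNS})
    return df.astype(
        {
            "index": int,
            "valid": bool,
            "lp_silent": bool,
            "extra_lp": int,
            "invalid_reason": str,
        },
        errors="ignore",
    )


def build_cycles(
    pd_bursts: pd.DataFrame,
    lp_bursts: pd.DataFrame,
    gap_factor: float = 5.0,
    median_window: int = 11,
) -> pd.DataFrame:
    """Build the cycle table from per-unit burst tables.

    ``pd_bursts``/``lp_bursts`` are DataFrames with ``start``/``end`` columns
    (as produced by :func:`pyloric.bursts.segment_bursts`), ordered and
    non-overlapping.  Fewer than 2 PD bursts yields an empty table.
    """
    if len(pd_bursts) < 2:
        return _empty_table()
    pd_start = pd_bursts["start"].to_numpy(dtype=float)
    pd_end = pd_bursts["end"].to_numpy(dtype=float)
    if np.any(np.diff(pd_start) <= 0):
        raise ValueError("PD bursts must be ordered with increasing starts")

    n = len(pd_start) - 1
    starts = pd_start[:n]
    nexts = pd_start[1:]
    periods = nexts - starts
    freqs = 1.0 / periods

    # trailing median of the preceding up-to-`median_window` periods; the
    # first cycle has no history and can never be a gap break
    trail = (
        pd.Series(periods).rolling(median_window, min_periods=1).median().shift(1).to_numpy()
    )
    gap = np.zeros(n, dtype=bool)
    known = ~np.isnan(trail)
    gap[known] = periods[known] > gap_factor * trail[known]

    # LP assignment: first LP burst starting in [pd_start_i, pd_start_{i+1})
    if len(lp_bursts):
        lp_start_all = lp_bursts["start"].to_numpy(dtype=float)
        lp_end_all = lp_bursts["end"].to_numpy(dtype=float)
        i0 = np.searchsorted(lp_start_all, starts, side="left")
        i1 = np.searchsorted(lp_start_all, nexts, side="left")
        has_lp = i1 > i0
        extra = np.maximum(i1 - i0 - 1, 0)
        lp_s = np.full(n, np.nan)
        lp_e = np.full(n, np.nan)
        sel = np.minimum(i0, len(lp_start_all) - 1)
        lp_s[has_lp] = lp_start_all[sel[has_lp]]
        lp_e[has_lp] = lp_end_all[sel[has_lp]]
    else:
        has_lp = np.zeros(n, dtype=bool)
        extra = np.zeros(n, dtype=int)
        lp_s = np.full(n, np.nan)
        lp_e = np.full(n, np.nan)

    pd_off = (pd_end[:n] - starts) / periods
    lp_on = (lp_s - starts) / periods
    lp_off = (lp_e - starts) / periods

    reason = np.where(gap, "gap", "")
    valid = ~gap
    return pd.DataFrame(
        {
            "index": np.arange(n),
            "pd_start": starts,
            "pd_end": pd_end[:n],
            "lp_start": lp_s,
            "lp_end": lp_e,
            "period": periods,
            "frequency": freqs,
            "pd_off_phase": pd_off,
            "lp_on_phase": lp_on,
            "lp_off_phase": lp_off,
            "valid": valid,
            "lp_silent": ~has_lp,
            "extra_lp": extra.astype(int),
            "invalid_reason": reason,
        }
    )


def filter_cycles(
    cycles: pd.DataFrame, min_freq: float = 0.02, max_freq: float = 3.0
) -> pd.DataFrame:
    """Mark cycles invalid outside ``[min_freq, max_freq]`` or with LP overrun.

    Nothing is deleted: flags and reasons are updated on a copy.  An LP burst
    ending at or after the next PD start (``lp_off_phase >= 1``) marks the
    cycle invalid with reason ``"lp_overrun"``.
    """
    if not (0 < min_freq < max_freq):
        raise ValueError("need 0 < min_freq < max_freq")
    out = cycles.copy()
    f = out["frequency"].to_numpy()
    bad_freq = (f < min_freq) | (f > max_freq)
    lp_over = out["lp_off_phase"].to_numpy() >= 1.0  # NaN compares False

    reasons = out["invalid_reason"].to_numpy(dtype=object)
    for mask, tag in ((bad_freq, "freq_range"), (lp_over, "lp_overrun")):
        for i in np.flatnonzero(mask):
            reasons[i] = f"{reasons[i]};{tag}" if reasons[i] else tag
    out["invalid_reason"] = reasons
    out["valid"] = out["valid"].to_numpy() & ~bad_freq & ~lp_over
    return out


def phase_frequency_regression(
    frequency: np.ndarray, phase: np.ndarray
) -> dict[str, float]:
    """OLS fit of phase on frequency with Pearson R and p.

    Returns ``{"slope", "intercept", "r", "p", "n"}``.  Pairs with a
    non-finite member are dropped; fewer than 3 remaining points or zero
    frequency variance is an error.
    """
    x = np.asarray(frequency, dtype=float)
    y = np.asarray(phase, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 finite points")
    vx = x.var()
    if vx == 0:
        raise ValueError("zero variance in frequency: slope undefined")
    slope = float(np.cov(x, y, bias=True)[0, 1] / vx)
    intercept = float(y.mean() - slope * x.mean())
    if y.var() == 0:
        r, p = 0.0, 1.0
    else:
        res = _stats.pearson_corr(x, y)
        r, p = res.statistic, res.p
    return {"slope": slope, "intercept": intercept, "r": r, "p": p, "n": int(x.size)}
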