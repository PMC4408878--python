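"""Independent brute-force oracles used by the test suite.

Deliberately naive re-implementations (pure-Python loops, no incremental
updates, no shared code with the package) of the rules the package
implements with vectorised shortcuts.
"""

from __future__ import annotations


def bout_events_bruteforce(freqs, lookback=10, lookahead=3, rel_increase=0.40, strict=False):
    """Re-evaluate the trailing-mean bout rule at every index, then merge.

    Returns a list of ``(detect_index, extent_first, extent_last)``.
    """
    f = list(map(float, freqs))
    n = len(f)
    fires = []
    for i in range(lookback, n - lookahead + 1):
        background = sum(f[i - lookback : i]) / lookback
        threshold = (1.0 + rel_increase) * background
        ok = True
        for j in range(lookahead):
            v = f[i + j]
            if (v <= threshold) if strict else (v < threshold):
                ok = False
                break
        if ok:
            fires.append(i)
    events = []
    for i in fires:
        if events and i == events[-1][-1] + 1:
            events[-1][-1] = i
        else:
            events.append([i, i])
    return [(a, a, b + lookahead - 1) for a, b in events]


def bursts_bruteforce(times, max_isi, min_spikes=2):
    """Enumerate maximal runs with every gap <= max_isi, drop short runs.

    Returns a list of ``(start, end, n_spikes)``.
    """
    t = list(map(float, times))
    if not t:
        return []
    runs = [[t[0]]]
    for prev, cur in zip(t, t[1:]):
        if cur - prev <= max_isi:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    return [(r[0], r[-1], len(r)) for r in runs if len(r) >= min_spikes]


def fastest_window_bruteforce(
    t, f, t_dec, window_h=5.0, horizon_h=120.0, step_h=0.1, min_occupancy=0.5
):
    """Evaluate every candidate window with boolean masks; earliest-start ties.

    ``t``/``f`` are valid-cycle PD-start times (s) and frequencies, sorted.
    Returns ``(start_s, mean_freq)`` or ``None``.
    """
    win = window_h * 3600.0
    step = step_h * 3600.0
    if not len(t):
        return None
    limit = min(t_dec + horizon_h * 3600.0, max(t))
    if limit - t_dec < win:
        return None
    n_steps = int((limit - t_dec - win) / step + 1e-9) + 1
    n_sub = int(round(win / step))
    best = None
    for k in range(n_steps):
        w0 = t_dec + k * step
        w1 = w0 + win
        sel = [fi for ti, fi in zip(t, f) if w0 <= ti < w1]
        if not sel:
            continue
        occupied = set()
        for ti in t:
            if w0 <= ti < w1:
                occupied.add(int((ti - w0) / step))
        if len(occupied) < min_occupancy * n_sub:
            continue
        mean_f = sum(sel) / len(sel)
        if best is None or mean_f > best[1] + 1e-15:
            best = (w0, mean_f)
    return best


def splitplot_ss_bruteforce(values, groups):
    """Split-plot sums of squares from cell and marginal means, explicit loops.

    ``values``: list of per-subject lists (all the same length k);
    ``groups``: per-subject labels.  Returns a dict of SS components.
    """
    n = len(values)
    k = len(values[0])
    labels = sorted(set(groups))
    grand = sum(sum(row) for row in values) / (n * k)

    subj_mean = [sum(row) / k for row in values]
    time_mean = [sum(values[s][t] for s in range(n)) / n for t in range(k)]
    group_subjects = {g: [s for s in range(n) if groups[s] == g] for g in labels}
    group_mean = {
        g: sum(subj_mean[s] for s in group_subjects[g]) / len(group_subjects[g])
        for g in labels
    }
    cell_mean = {
        (g, t): sum(values[s][t] for s in group_subjects[g]) / len(group_subjects[g])
        for g in labels
        for t in range(k)
    }

    ss_total = sum((values[s][t] - grand) ** 2 for s in range(n) for t in range(k))
    ss_group = sum(
        k * len(group_subjects[g]) * (group_mean[g] - grand) ** 2 for g in labels
    )
    ss_subj_within = sum(
        k * (subj_mean[s] - group_mean[g]) ** 2
        for g in labels
        for s in group_subjects[g]
    )
    ss_time = sum(n * (time_mean[t] - grand) ** 2 for t in range(k))
    ss_inter = sum(
        len(group_subjects[g])
        * (cell_mean[(g, t)] - group_mean[g] - time_mean[t] + grand) ** 2
        for g in labels
        for t in range(k)
    )
    ss_err2 = ss_total - ss_group - ss_subj_within - ss_time - ss_inter
    return {
        "group": ss_group,
        "subjects_within_groups": ss_subj_within,
        "time": ss_time,
        "interaction": ss_inter,
        "time_x_subjects": ss_err2,
        "total": ss_total,
    }
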