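"""Independent brute-force oracles for the detectors and the engine.

These re-derive every decision with plain loops from first principles and
must stay independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np


def oracle_amplitude_jump(values, dt, jump_threshold, base_window_s=1.0,
                          recovery_threshold=0.2, merge_gap=2):
    """Criterion-1 decision by literal enumeration of consecutive pairs.

    Returns (flagged, severity_or_None).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    over = []
    for i in range(n - 1):
        if abs(values[i + 1] - values[i]) > jump_threshold:
            over.append(i)
    # group; merge runs separated by fewer than merge_gap sub-threshold diffs
    events = []
    for i in over:
        if events and i - events[-1][-1] - 1 < merge_gap:
            events[-1].append(i)
        else:
            events.append([i])
    w = max(int(round(base_window_s / dt)), 1)
    shifts = []
    for ev in events:
        onset, ending = ev[0], ev[-1] + 1
        before = values[max(onset - w, 0):onset]
        after = values[ending:ending + w]
        if before.size == 0:
            before = values[onset:onset + 1]
        if after.size == 0:
            after = values[ending - 1:ending]
        shifts.append(abs(np.mean(after) - np.mean(before)))
    noise = [s for s in shifts if s > recovery_threshold]
    if noise:
        return True, max(noise)
    return False, None


def oracle_baseline_slope(values, times):
    """Closed-form least-squares slope over the prestimulus samples."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    mask = times < 0
    t, x = times[mask], values[mask]
    tbar, xbar = t.mean(), x.mean()
    return float(((t - tbar) * (x - xbar)).sum() / ((t - tbar) ** 2).sum())


def _pearson(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def _quartile_linear(sorted_vals, p):
    """Quartile by linear interpolation at position p*(n-1), 0-based."""
    n = len(sorted_vals)
    pos = p * (n - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def oracle_low_correlation(values, k_iqr):
    """Criterion-3 flags by independent pairwise-correlation recomputation.

    Returns dict {row_index: severity} of flagged rows.
    """
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    sums = []
    for i in range(m):
        s = 0.0
        for j in range(m):
            if j != i:
                s += _pearson(values[i], values[j])
        sums.append(s)
    srt = sorted(sums)
    q1 = _quartile_linear(srt, 0.25)
    q3 = _quartile_linear(srt, 0.75)
    fence = q1 - k_iqr * (q3 - q1)
    return {i: fence - s for i, s in enumerate(sums) if s < fence}


def oracle_five_step(n_epochs, stage_flags, stage_severity, acceptance):
    """Literal simulation of the five-step rejection process plus ranking.

    ``stage_flags[k]`` is the set of epochs criterion k would flag among the
    retained (intersection taken here); ``stage_severity(stage, epoch)``
    gives the flag severity. ``acceptance`` is an int floor or None.
    Returns (retained_sorted, rejected_dict).
    """
    retained = list(range(n_epochs))
    recorded = []  # (stage, epoch, severity)
    rejected = {}
    for stage, pattern in enumerate(stage_flags):
        flagged = sorted(set(pattern) & set(retained))           # process 1
        remaining_after = len(retained) - len(flagged)           # process 2
        floor = 0 if acceptance is None else acceptance
        if remaining_after >= floor:                             # process 3
            for e in flagged:                                    # process 4
                retained.remove(e)
                rejected[e] = f"criterion_{stage + 1}"
        else:                                                    # record only
            for e in flagged:
                recorded.append((stage, e, stage_severity(stage, e)))
        # process 5: next criterion sees only survivors (loop continues)
    if acceptance is not None:
        recorded = [r for r in recorded if r[1] in retained]
        levels = {}
        for _, e, _ in recorded:
            levels[e] = levels.get(e, 0) + 1
        # within-criterion severity ranks, average ties, ascending severity
        rank_sum = {e: 0.0 for e in levels}
        for stage in set(r[0] for r in recorded):
            entries = [r for r in recorded if r[0] == stage]
            sevs = [r[2] for r in entries]
            for (_, e, s) in entries:
                below = sum(1 for v in sevs if v < s)
                equal = sum(1 for v in sevs if v == s)
                rank_sum[e] += below + (equal + 1) / 2.0
        order = sorted(levels, key=lambda e: (-levels[e], -rank_sum[e], e))
        for e in order:
            if len(retained) <= acceptance:
                break
            retained.remove(e)
            rejected[e] = "ranking"
    return sorted(retained), rejected
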