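"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the interval arithmetic of the library: the episode
oracle is a minute-by-minute state machine, the effective-escalation oracle a
direct rule walk, and the median-filter oracle an explicit per-minute window
scan.  They define the expected behaviour; the library must match them.
"""

from __future__ import annotations

import numpy as np


def effective_eocs_sweep(events: list[tuple[int, str]], rrt_sep: int = 1440) -> list[int]:
    """Rule walk over (t, kind) events; returns effective escalation times."""
    EOC = {"rrt", "icu_unplanned", "emergency_surgery", "death"}
    out: list[int] = []
    censor = None
    closed = False
    for t, kind in events:
        if censor is not None and t > censor:
            continue
        if kind in ("discharge", "monitoring_stop"):
            censor = t if censor is None else min(censor, t)
        elif kind in EOC and not closed:
            if not out:
                out.append(t)
                closed = kind != "rrt"
            elif kind == "rrt" and t - out[-1] >= rrt_sep:
                out.append(t)
    return out


def episodes_sweep(alerts: list[int], eocs: list[tuple[int, str]], censor: int,
                   window: int = 240, max_neg: int = 480):
    """Minute-by-minute episode construction and classification.

    Returns (periods, segments, counts) with periods as
    (start, end, truncated) triples, segments as (start, end), and counts as
    a dict with tp/fp/tn/fn.
    """
    eoc_times = sorted(t for t, _ in eocs)
    terminal = min((t for t, k in eocs if k != "rrt"), default=None)
    kept = sorted(t for t in set(alerts)
                  if (t < censor or (terminal is not None and t == terminal))
                  and (terminal is None or t <= terminal))
    alert_set = set(kept)
    eoc_set = set(eoc_times)

    periods: list[tuple[int, int, bool]] = []
    start = end = None
    horizon = max([censor] + [t + window + 1 for t in kept])
    for t in range(horizon + 1):
        if start is not None and t == end:
            periods.append((start, end, False))
            start = end = None
        if t in alert_set:
            if start is None:
                start, end = t, t + window
            else:
                end = t + window
        if t in eoc_set and start is not None and start <= t <= end:
            periods.append((start, t, True))
            start = end = None
    if start is not None:
        periods.append((start, end, False))
    # clip to the evaluable timeline
    clipped = []
    for s, e, tr in periods:
        if s > censor:
            continue
        clipped.append((s, e if tr else min(e, censor), tr))
    periods = clipped

    covered = np.zeros(censor + 1, dtype=bool)
    for s, e, _ in periods:
        covered[s:min(e, censor)] = True
    segments: list[tuple[int, int]] = []
    t = 0
    while t < censor:
        if covered[t]:
            t += 1
            continue
        gs = t
        while t < censor and not covered[t]:
            t += 1
        ge = t
        c = gs
        while c < ge:
            segments.append((c, min(c + max_neg, ge)))
            c = min(c + max_neg, ge)

    tp = fp = tn = fn = 0
    matched_periods = set()
    fn_segments = set()
    for e_t in eoc_times:
        hit = next((i for i, (s, e, tr) in enumerate(periods)
                    if s <= e_t < e or (tr and e_t == e)), None)
        if hit is not None:
            tp += 1
            matched_periods.add(hit)
            continue
        seg = next((i for i, (s, e) in enumerate(segments) if s <= e_t < e), None)
        if seg is None:
            seg = next((i for i, (s, e) in enumerate(segments) if e_t == e), None)
        if seg is None:
            raise AssertionError(f"oracle: escalation at {e_t} uncovered")
        fn += 1
        fn_segments.add(seg)
    fp = len(periods) - len(matched_periods)
    tn = len(segments) - len(fn_segments)
    return periods, segments, {"tp": tp, "fp": fp, "tn": tn, "fn": fn}


def median_filter_sweep(t: np.ndarray, values: np.ndarray, w: int) -> np.ndarray:
    """Per-minute window scan median over available values in [t - w, t + w]."""
    out = np.full(len(t), np.nan)
    for i, ti in enumerate(t):
        sel = (t >= ti - w) & (t <= ti + w) & ~np.isnan(values)
        if sel.any():
            out[i] = np.median(values[sel])
    return out


def quartiles_sorted(values: list[float]) -> tuple[float, float, float]:
    """Sort-based linear-interpolation quartiles (q1, median, q3)."""
    v = sorted(values)
    n = len(v)

    def q(p: float) -> float:
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    return q(0.25), q(0.5), q(0.75)


def exact_mw_p(x: list[float], y: list[float]) -> float:
    """Exhaustive permutation two-sided p for the rank-sum U statistic."""
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.array(list(x) + list(y), dtype=float)
    n, mx = len(pooled), len(x)
    ranks = rankdata(pooled)
    mu = mx * (len(y)) / 2.0

    def u_of(idx: tuple[int, ...]) -> float:
        return ranks[list(idx)].sum() - mx * (mx + 1) / 2.0

    u_obs = u_of(tuple(range(mx)))
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n), mx):
        total += 1
        if abs(u_of(idx) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total
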