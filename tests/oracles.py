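"""Independent brute-force oracles used to cross-check the implementations.

Every function here recomputes a quantity by direct enumeration or day-by-day
scanning, deliberately avoiding the vectorized/incremental code paths of the
package.
"""

from __future__ import annotations

import itertools

import numpy as np


def km_bruteforce(durations, events):
    """Product-limit estimate by explicit risk-set recomputation."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    times = sorted(set(durations[events]))
    out_t, out_s, out_n, out_d = [], [], [], []
    s = 1.0
    for t in times:
        n = int(np.sum(durations >= t))
        d = int(np.sum(events & (durations == t)))
        s *= 1.0 - d / n
        out_t.append(t)
        out_s.append(s)
        out_n.append(n)
        out_d.append(d)
    return np.array(out_t), np.array(out_s), np.array(out_n), np.array(out_d)


def aj_bruteforce(durations, codes):
    """Aalen-Johansen CIFs by explicit per-time risk-set recomputation."""
    durations = np.asarray(durations, dtype=float)
    codes = np.asarray(codes, dtype=int)
    causes = sorted(c for c in set(codes) if c != 0)
    times = sorted(set(durations[codes > 0]))
    s_prev = 1.0
    cif = {c: [] for c in causes}
    surv = []
    for t in times:
        n = int(np.sum(durations >= t))
        d_all = int(np.sum((codes > 0) & (durations == t)))
        for c in causes:
            d_c = int(np.sum((codes == c) & (durations == t)))
            prev = cif[c][-1] if cif[c] else 0.0
            cif[c].append(prev + s_prev * d_c / n)
        s_prev *= 1.0 - d_all / n
        surv.append(s_prev)
    return (np.array(times), np.array(surv),
            {c: np.array(v) for c, v in cif.items()})


def coverage_bruteforce(days, coverage_days, merge_gap_days):
    """Coverage intervals via a day-by-day bitmap plus gap bridging."""
    days = sorted(set(int(d) for d in days))
    if not days:
        return []
    lo, hi = days[0], days[-1] + coverage_days
    covered = np.zeros(hi - lo, dtype=bool)
    for d in days:
        covered[d - lo: d - lo + coverage_days] = True
    # runs of covered days
    runs = []
    i = 0
    while i < len(covered):
        if covered[i]:
            j = i
            while j < len(covered) and covered[j]:
                j += 1
            runs.append([i + lo, j + lo])
            i = j
        else:
            i += 1
    # bridge gaps <= merge_gap_days
    merged = [runs[0]]
    for a, b in runs[1:]:
        if a - merged[-1][1] <= merge_gap_days:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def belatacept_bruteforce(stays, deliveries, config):
    """Three-clause belatacept call by exhaustive triple enumeration.

    ``stays``: list of (day, is_chemo, diagnosis_codes);
    ``deliveries``: list of (day, drug_class).
    Returns (positive, index_hosp_day, clause1, clause2, clause3, direct).
    """
    from ktxclaims.config import group_of, BELATACEPT, MTORI, ANTIMETABOLITE, CNI

    w = config.windows
    prefixes = tuple(config.transplant_diagnosis_codes)
    qual = [day for day, chemo, codes in stays
            if chemo and any(c.startswith(p) for c in codes for p in prefixes)]
    hosp_candidates = []
    for triple in itertools.combinations(sorted(qual), w.belatacept_min_stays):
        if max(triple) - min(triple) <= w.belatacept_span_days:
            hosp_candidates.append(min(triple))
    clause1 = bool(hosp_candidates)
    h = min(hosp_candidates) if clause1 else None

    direct = any(cls == BELATACEPT for _, cls in deliveries)
    clause2 = clause3 = False
    if clause1:
        clause2 = any(group_of(cls) in (MTORI, ANTIMETABOLITE)
                      and h <= day <= h + w.companion_window_days
                      for day, cls in deliveries)
        clause3 = not any(group_of(cls) == CNI
                          and h + w.cni_free_start_day <= day < h + w.cni_free_end_day
                          for day, cls in deliveries)
    positive = (clause1 and clause2 and clause3) or direct
    return positive, h, clause1, clause2, clause3, direct


def regimen_periods_bruteforce(group_intervals, min_days, nonsteroid_of):
    """Constant-class-set periods by day scanning, with the <30-day
    multi-class reattribution rule applied post hoc.

    ``group_intervals``: dict group -> list of (start, end) half-open.
    Returns list of (start, end, frozenset groups).
    """
    points = sorted({x for ivs in group_intervals.values() for ab in ivs for x in ab})
    if not points:
        return []
    lo, hi = points[0], points[-1]
    day_sets = []
    for day in range(lo, hi):
        active = frozenset(g for g, ivs in group_intervals.items()
                           if any(a <= day < b for a, b in ivs))
        day_sets.append(active)
    # compress to runs, dropping uncovered days
    runs = []
    for i, s in enumerate(day_sets):
        if not s:
            continue
        day = i + lo
        if runs and runs[-1][2] == s and runs[-1][1] == day:
            runs[-1][1] = day + 1
        else:
            runs.append([day, day + 1, s])
    changed = True
    while changed:
        changed = False
        for i, (a, b, s) in enumerate(runs):
            if len(nonsteroid_of(s)) >= 2 and b - a < min_days:
                if i > 0 and runs[i - 1][1] == a:
                    runs[i - 1][1] = b
                elif i + 1 < len(runs) and runs[i + 1][0] == b:
                    runs[i + 1][0] = a
                else:
                    continue
                del runs[i]
                changed = True
                break
        i = 0
        while i + 1 < len(runs):
            if runs[i][2] == runs[i + 1][2] and runs[i][1] == runs[i + 1][0]:
                runs[i][1] = runs[i + 1][1]
                del runs[i + 1]
                changed = True
            else:
                i += 1
    return [(a, b, s) for a, b, s in runs]
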