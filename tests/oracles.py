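"""Independent brute-force references used by the test suite.

These stay deliberately naive (explicit loops, fixpoint iteration) so
they share no code path with the implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def mk_brute(values):
    """Mann-Kendall by explicit pairwise loops + textbook tie formula."""
    x = [v for v in values if not (isinstance(v, float) and math.isnan(v))]
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            if x[j] > x[i]:
                s += 1
            elif x[j] < x[i]:
                s -= 1
    tie_term = 0
    for v in set(x):
        t = x.count(v)
        if t > 1:
            tie_term += t * (t - 1) * (2 * t + 5)
    var = (n * (n - 1) * (2 * n + 5) - tie_term) / 18
    if var == 0:
        z = 0.0
    elif s > 0:
        z = (s - 1) / math.sqrt(var)
    elif s < 0:
        z = (s + 1) / math.sqrt(var)
    else:
        z = 0.0
    p = 2 * stats.norm.sf(abs(z))
    return s, var, z, p


def runs_brute(mask):
    """Maximal True runs by linear scan."""
    runs, start = [], None
    for i, v in enumerate(list(mask) + [False]):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    return runs


def bouts_brute(mask, min_bout=10, merge_gap=1, merge_before_filter=True):
    """Run-merge-filter bout enumerator: exhaustive fixpoint merging."""

    def merge_fixpoint(intervals):
        if merge_gap <= 0:
            return list(intervals)
        intervals = list(intervals)
        changed = True
        while changed:
            changed = False
            for i in range(len(intervals) - 1):
                (s1, e1), (s2, e2) = intervals[i], intervals[i + 1]
                if s2 - e1 <= merge_gap:
                    intervals[i : i + 2] = [(s1, e2)]
                    changed = True
                    break
        return intervals

    runs = runs_brute(mask)
    if merge_before_filter:
        merged = merge_fixpoint(runs)
        return [(s, e) for s, e in merged if e - s >= min_bout]
    qualifying = [(s, e) for s, e in runs if e - s >= min_bout]
    return merge_fixpoint(qualifying)
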