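"""Independent brute-force reference implementations used as oracles.

Deliberately naive (plain Python loops, no vectorization, no code shared
with the package) so they can serve as an independent check of the
confinement-ratio phase parser and of the exact Mann-Whitney p-value.
"""

from __future__ import annotations

import math
from itertools import combinations


def reference_confinement_ratio(xs, ys, window: int) -> list[float]:
    """Windowed net-over-path ratio, computed by direct summation."""
    n = len(xs)
    half = window // 2
    out = []
    for i in range(n):
        if n < window:
            a, b = 0, n - 1
        else:
            a, b = max(0, i - half), min(n - 1, i + half)
        path = 0.0
        for j in range(a, b):
            path += math.hypot(xs[j + 1] - xs[j], ys[j + 1] - ys[j])
        net = math.hypot(xs[b] - xs[a], ys[b] - ys[a])
        out.append(net / path if path > 0 else 0.0)
    return out


def _runs(labels):
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append([start, i - 1, labels[start]])
            start = i
    return runs


def reference_phase_labels(xs, ys, window: int, threshold: float, min_phase: int):
    """Threshold the reference ratio, then merge short runs: repeatedly flip
    the earliest shortest run below ``min_phase`` until all runs are long
    enough or one run remains."""
    ratios = reference_confinement_ratio(xs, ys, window)
    labels = [r > threshold for r in ratios]
    while True:
        runs = _runs(labels)
        if len(runs) <= 1:
            break
        lengths = [e - s + 1 for s, e, _ in runs]
        shortest = min(lengths)
        if shortest >= min_phase:
            break
        s, e, val = runs[lengths.index(shortest)]
        for i in range(s, e + 1):
            labels[i] = not val
    return labels


def mann_whitney_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating every assignment of the
    pooled values to the two groups (tie-free data assumed)."""
    pooled = list(a) + list(b)
    na, nb = len(a), len(b)
    mu = na * nb / 2.0

    def u_of(group_a):
        rest = [pooled[i] for i in range(len(pooled)) if i not in group_a]
        vals = [pooled[i] for i in group_a]
        return sum(1 for x in vals for y in rest if x > y)

    u_obs = sum(1 for x in a for y in b if x > y)
    dev = abs(u_obs - mu)
    hits = 0
    total = 0
    for idx in combinations(range(len(pooled)), na):
        total += 1
        if abs(u_of(set(idx)) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total
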