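"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain nested loops / direct
formula evaluation, sharing no code with the package implementation.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def in_grid(p, shape):
    return all(0 <= c < n for c, n in zip(p, shape))


def bf_glcm(levels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Symmetric co-occurrence counts: each ordered pair along +/-direction."""
    m = np.zeros((n_levels, n_levels), dtype=np.int64)
    shape = levels.shape
    for p in product(*(range(n) for n in shape)):
        if levels[p] == 0:
            continue
        for sign in (1, -1):
            q = tuple(c + sign * d for c, d in zip(p, direction))
            if in_grid(q, shape) and levels[q] > 0:
                m[levels[p] - 1, levels[q] - 1] += 1
    return m


def bf_glrlm(levels: np.ndarray, n_levels: int, direction, max_run: int) -> np.ndarray:
    """Run-length counts by scanning whole grid lines along the direction."""
    m = np.zeros((n_levels, max_run), dtype=np.int64)
    shape = levels.shape
    starts = [
        p
        for p in product(*(range(n) for n in shape))
        if not in_grid(tuple(c - d for c, d in zip(p, direction)), shape)
    ]
    for start in starts:
        line = []
        p = start
        while in_grid(p, shape):
            line.append(levels[p])
            p = tuple(c + d for c, d in zip(p, direction))
        i = 0
        while i < len(line):
            if line[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < len(line) and line[j + 1] == line[i]:
                j += 1
            m[line[i] - 1, j - i] += 1
            i = j + 1
    return m


NEIGH_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def bf_glszm(levels: np.ndarray, n_levels: int, max_zone: int) -> np.ndarray:
    """Size-zone counts via breadth-first flood fill (26-connectivity)."""
    m = np.zeros((n_levels, max_zone), dtype=np.int64)
    shape = levels.shape
    seen = set()
    for p in product(*(range(n) for n in shape)):
        if levels[p] == 0 or p in seen:
            continue
        lev = levels[p]
        queue, zone = [p], set()
        seen.add(p)
        while queue:
            q = queue.pop()
            zone.add(q)
            for d in NEIGH_26:
                r = tuple(c + o for c, o in zip(q, d))
                if in_grid(r, shape) and r not in seen and levels[r] == lev:
                    seen.add(r)
                    queue.append(r)
        m[lev - 1, len(zone) - 1] += 1
    return m


def bf_gldm(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    m = np.zeros((n_levels, 27), dtype=np.int64)
    shape = levels.shape
    for p in product(*(range(n) for n in shape)):
        if levels[p] == 0:
            continue
        dep = 0
        for d in NEIGH_26:
            q = tuple(c + o for c, o in zip(p, d))
            if in_grid(q, shape) and levels[q] > 0 and abs(int(levels[q]) - int(levels[p])) <= alpha:
                dep += 1
        m[levels[p] - 1, dep] += 1
    return m


def bf_ngtdm(levels: np.ndarray, n_levels: int):
    s = np.zeros(n_levels)
    n = np.zeros(n_levels, dtype=np.int64)
    shape = levels.shape
    for p in product(*(range(nn) for nn in shape)):
        if levels[p] == 0:
            continue
        neigh = [
            levels[tuple(c + o for c, o in zip(p, d))]
            for d in NEIGH_26
            if in_grid(tuple(c + o for c, o in zip(p, d)), shape)
        ]
        neigh = [v for v in neigh if v > 0]
        if not neigh:
            continue
        s[levels[p] - 1] += abs(levels[p] - sum(neigh) / len(neigh))
        n[levels[p] - 1] += 1
    return s, n


def bf_oneway_anova(x: np.ndarray):
    """MSB, MSW by direct sum-of-squares decomposition."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    ssb = 0.0
    ssw = 0.0
    for i in range(n):
        mi = x[i].sum() / k
        ssb += k * (mi - grand) ** 2
        for j in range(k):
            ssw += (x[i, j] - mi) ** 2
    return ssb / (n - 1), ssw / (n * (k - 1))


def bf_spearman(x, y) -> float:
    """Rank correlation by explicit average ranking + Pearson formula."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return np.array(r)

    rx, ry = ranks(list(x)), ranks(list(y))
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
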