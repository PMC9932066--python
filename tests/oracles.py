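"""Independent brute-force oracles used to validate the metric
implementations.  Everything here is deliberately naive: plain loops,
exhaustive enumeration, direct evaluation of definitions."""

from __future__ import annotations

import itertools
import math

import numpy as np


def nodf_brute(mat: np.ndarray) -> float:
    """NODF by direct evaluation of the paired-overlap definition."""
    b = np.asarray(mat) > 0
    total = 0.0
    pairs = 0
    for axis_mat in (b, b.T):
        n = axis_mat.shape[0]
        for i in range(n):
            for k in range(i + 1, n):
                pairs += 1
                fi = axis_mat[i].sum()
                fk = axis_mat[k].sum()
                if fi == fk:
                    continue
                hi, lo = (i, k) if fi > fk else (k, i)
                shared = int((axis_mat[hi] & axis_mat[lo]).sum())
                total += 100.0 * shared / axis_mat[lo].sum()
    return total / pairs


def enumerate_tables(row_totals, col_totals):
    """All nonnegative integer tables with the given margins, cell by cell."""
    rows = list(row_totals)
    cols = list(col_totals)
    R, C = len(rows), len(cols)

    def rec(i, remaining_cols, acc):
        if i == R:
            yield np.array(acc, dtype=int).reshape(R, C)
            return
        for combo in _row_fills(rows[i], remaining_cols):
            yield from rec(
                i + 1,
                [r - n for r, n in zip(remaining_cols, combo)],
                acc + list(combo),
            )

    def _row_fills(total, caps):
        if len(caps) == 1:
            if total <= caps[0]:
                yield (total,)
            return
        for first in range(min(total, caps[0]) + 1):
            for rest in _row_fills(total - first, caps[1:]):
                yield (first,) + rest

    yield from rec(0, cols, [])


def table_log_prob(table: np.ndarray) -> float:
    """Log probability of a table under the fixed-margin independence
    (multiple hypergeometric) distribution."""
    t = np.asarray(table, dtype=int)
    m = int(t.sum())
    lp = -math.lgamma(m + 1)
    for r in t.sum(axis=1):
        lp += math.lgamma(int(r) + 1)
    for c in t.sum(axis=0):
        lp += math.lgamma(int(c) + 1)
    for x in t.ravel():
        lp -= math.lgamma(int(x) + 1)
    return lp


def shannon_entropy(table: np.ndarray) -> float:
    t = np.asarray(table, dtype=float)
    p = t[t > 0] / t.sum()
    return float(-(p * np.log(p)).sum())


def entropy_extremes_brute(row_totals, col_totals) -> tuple[float, float]:
    """(min, max) Shannon entropy over all integer tables with the margins."""
    hs = [shannon_entropy(t) for t in enumerate_tables(row_totals, col_totals)]
    return min(hs), max(hs)


def kl_divergence(alloc: np.ndarray, q: np.ndarray) -> float:
    a = np.asarray(alloc, dtype=float)
    tot = a.sum()
    out = 0.0
    for x, qi in zip(a, q):
        if x > 0:
            p = x / tot
            out += p * math.log(p / qi)
    return out


def dprime_extremes_brute(total: int, row_totals) -> tuple[float, float]:
    """(min, max) KL divergence over integer allocations of ``total`` visits;
    the maximum respects per-plant caps (plant totals), the minimum is
    unconstrained apart from the sum."""
    r = np.asarray(row_totals, dtype=float)
    q = r / r.sum()
    R = len(r)

    def allocations(caps):
        def rec(i, left):
            if i == R - 1:
                if left <= caps[-1]:
                    yield (left,)
                return
            for n in range(min(left, caps[i]) + 1):
                for rest in rec(i + 1, left - n):
                    yield (n,) + rest

        yield from rec(0, total)

    dmin = min(kl_divergence(np.array(a), q) for a in allocations([total] * R))
    dmax = max(
        kl_divergence(np.array(a), q)
        for a in allocations([int(x) for x in row_totals])
    )
    return dmin, dmax


def set_partitions(n: int):
    """All partitions of range(n) as label vectors (restricted growth)."""
    labels = [0] * n

    def rec(i, maxlab):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(maxlab + 2):
            labels[i] = lab
            yield from rec(i + 1, max(maxlab, lab))

    yield from rec(1, 0) if n > 1 else iter([(0,) * n])


def modularity_exhaustive(mat: np.ndarray) -> float:
    """Maximum Barber modularity over all joint row/column partitions."""
    a = np.asarray(mat, dtype=float)
    R, C = a.shape
    m = a.sum()
    b = (a - np.outer(a.sum(axis=1), a.sum(axis=0)) / m) / m
    best = -np.inf
    for labels in set_partitions(R + C):
        lr = np.array(labels[:R])
        lc = np.array(labels[R:])
        q = b[lr[:, None] == lc[None, :]].sum()
        if q > best:
            best = q
    return float(best)


def point_segment_distance(p, a, b) -> float:
    """Distance from point p to segment ab, textbook projection formula."""
    p, a, b = (np.asarray(v, dtype=float) for v in (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else max(0.0, min(1.0, float((p - a) @ ab) / denom))
    return float(np.linalg.norm(p - (a + t * ab)))


def random_count_matrix(
    rng: np.random.Generator,
    max_rows: int = 4,
    max_cols: int = 4,
    max_total: int = 18,
) -> np.ndarray:
    """Small random count matrix without zero rows/columns."""
    while True:
        R = rng.integers(2, max_rows + 1)
        C = rng.integers(2, max_cols + 1)
        m = rng.integers(R + C, max_total + 1)
        cells = rng.multinomial(m, np.ones(R * C) / (R * C)).reshape(R, C)
        if (cells.sum(axis=1) > 0).all() and (cells.sum(axis=0) > 0).all():
            return cells
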