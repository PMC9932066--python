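"""Structural metrics for quantitative bipartite networks.

Implements the five classical plant-pollinator network descriptors:

* ``connectance`` - realised fraction of possible links;
* ``nodf`` - nestedness by overlap and decreasing fill (0-100, on the
  binarised matrix);
* ``h2prime`` - network-level specialisation: the two-dimensional Shannon
  entropy of the interaction frequencies standardised between the extreme
  entropies attainable under the observed margin totals (0 generalised,
  1 specialised);
* ``dprime`` - species-level specialisation: Kullback-Leibler divergence of
  a visitor's plant use from plant availability, standardised between its
  margin-constrained extremes;
* ``modularity`` - Barber-type weighted bipartite modularity maximised by
  simulated annealing over joint plant/visitor module assignments.

H2' and d' entropy/divergence extremes are computed over *integer* tables
with the observed margins: exactly (dynamic programming/greedy algorithms
that are provably optimal for these separable objectives) wherever the
state space permits, with documented greedy approximations for large
tables where exact search is infeasible.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .netbuild import BipartiteNetwork

__all__ = [
    "SAParams",
    "connectance",
    "nodf",
    "h2prime",
    "dprime",
    "dprime_all",
    "mean_dprime",
    "modularity",
    "modularity_q",
]


def _counts(net) -> np.ndarray:
    if isinstance(net, BipartiteNetwork):
        return net.counts
    return np.asarray(net, dtype=float)


# ------------------------------------------------------------- connectance

def connectance(net) -> float:
    """Number of realised links divided by the number of matrix cells."""
    a = _counts(net)
    return float(np.count_nonzero(a) / a.size)


# -------------------------------------------------------------------- NODF

def nodf(net) -> float:
    """Nestedness by overlap and decreasing fill, on the binarised matrix.

    Every unordered pair of rows (and of columns) contributes
    ``100 * shared presences / smaller fill`` when the two fills differ
    strictly, and 0 when they are equal; NODF is the mean contribution over
    all row pairs and column pairs.
    """
    a = _counts(net) > 0
    nr, nc = a.shape
    if nr < 2 and nc < 2:
        raise ValueError("NODF is undefined for a single row and column")

    def axis_sum(b: np.ndarray) -> tuple[float, int]:
        n = b.shape[0]
        if n < 2:
            return 0.0, 0
        fills = b.sum(axis=1)
        bi = b.astype(int)
        overlap = (bi @ bi.T).astype(float)
        fi = fills[:, None]
        fk = fills[None, :]
        smaller = np.minimum(fi, fk)
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.where(
                (fi != fk) & (smaller > 0), 100.0 * overlap / smaller, 0.0
            )
        iu = np.triu_indices(n, k=1)
        return float(contrib[iu].sum()), n * (n - 1) // 2

    srow, prow = axis_sum(a)
    scol, pcol = axis_sum(a.T)
    return (srow + scol) / (prow + pcol)


# ----------------------------------------------------- entropy extremes

def _xlogx(p: np.ndarray | float) -> np.ndarray | float:
    return np.where(np.asarray(p) > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)


def _matrix_entropy(a: np.ndarray) -> float:
    m = a.sum()
    p = a[a > 0] / m
    return float(-(p * np.log(p)).sum())


class _Budget:
    __slots__ = ("left",)

    def __init__(self, n: int):
        self.left = n

    def spend(self, k: int = 1) -> None:
        self.left -= k
        if self.left < 0:
            raise _BudgetExceeded


class _BudgetExceeded(Exception):
    pass


def _compositions(total: int, caps: tuple[int, ...]):
    """All ways to split `total` into len(caps) parts with part_k <= caps[k]."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    lo = max(0, total - sum(caps[1:]))
    hi = min(total, caps[0])
    for first in range(lo, hi + 1):
        for rest in _compositions(total - first, caps[1:]):
            yield (first,) + rest


def _entropy_extreme_exact(
    rows: tuple[int, ...], cols: tuple[int, ...], maximise: bool, budget: _Budget
) -> float:
    """Extreme Shannon entropy over integer tables with the given margins.

    Dynamic programme over rows; the state is the tuple of remaining column
    totals, which fully determines the optimal completion because the
    objective is additive over cells.  Raises ``_BudgetExceeded`` when the
    enumeration grows beyond the configured budget.
    """
    m = sum(rows)
    sign = 1.0 if maximise else -1.0

    def term(n: int) -> float:
        return 0.0 if n == 0 else -(n / m) * math.log(n / m)

    memo: dict[tuple[int, tuple[int, ...]], float] = {}

    def best(i: int, rem: tuple[int, ...]) -> float:
        if i == len(rows):
            return 0.0
        key = (i, rem)
        if key in memo:
            return memo[key]
        val = -math.inf
        for comp in _compositions(rows[i], rem):
            budget.spend()
            v = sign * sum(term(n) for n in comp) + best(
                i + 1, tuple(r - n for r, n in zip(rem, comp))
            )
            if v > val:
                val = v
        memo[key] = val
        return val

    return sign * best(0, tuple(cols))


def _max_entropy_greedy(rows: np.ndarray, cols: np.ndarray) -> float:
    """Greedy integer approximation of the maximum-entropy table.

    Starts from the floor of the continuous maximum-entropy (independence)
    table r_i c_j / m and assigns the remaining units one at a time to the
    margin-feasible cell furthest below its continuous target, keeping the
    table as close to proportionality as integrality allows.
    """
    m = rows.sum()
    target = np.outer(rows, cols) / m
    a = np.floor(target)
    rd = (rows - a.sum(axis=1)).astype(int)
    cd = (cols - a.sum(axis=0)).astype(int)
    while rd.sum() > 0:
        score = np.where((rd[:, None] > 0) & (cd[None, :] > 0), target - a, -np.inf)
        i, j = np.unravel_index(np.argmax(score), score.shape)
        a[i, j] += 1
        rd[i] -= 1
        cd[j] -= 1
    return _matrix_entropy(a)


def _min_entropy_greedy(rows: np.ndarray, cols: np.ndarray) -> float:
    """Greedy minimum-entropy table: repeatedly place the largest feasible
    block min(max remaining row, max remaining col) into one cell."""
    rd = rows.astype(int).copy()
    cd = cols.astype(int).copy()
    m = rows.sum()
    h = 0.0
    while rd.sum() > 0:
        i = int(np.argmax(rd))
        j = int(np.argmax(cd))
        n = min(rd[i], cd[j])
        h -= (n / m) * math.log(n / m)
        rd[i] -= n
        cd[j] -= n
    return h


@lru_cache(maxsize=4096)
def _entropy_bounds(rows: tuple[int, ...], cols: tuple[int, ...]) -> tuple[float, float]:
    """(H2min, H2max) over integer tables with the given margins.

    Margins are order-invariant for the extremes, so callers pass sorted
    tuples to maximise cache hits.  Exact dynamic programming on small
    tables (bounded dimensions and total, plus an enumeration budget as a
    backstop), greedy approximations beyond that.
    """
    m = sum(rows)
    small = len(rows) <= 5 and len(cols) <= 6 and m <= 28
    if small:
        try:
            hmax = _entropy_extreme_exact(rows, cols, True, _Budget(300_000))
            hmin = _entropy_extreme_exact(rows, cols, False, _Budget(300_000))
            return hmin, hmax
        except _BudgetExceeded:
            pass
    r = np.asarray(rows)
    c = np.asarray(cols)
    return _min_entropy_greedy(r, c), _max_entropy_greedy(r, c)


def h2prime(net) -> float:
    """Network-level specialisation H2' in [0, 1].

    Standardises the two-dimensional Shannon entropy of interaction
    frequencies between the minimum and maximum entropy attainable by an
    integer table with the observed row/column totals.  A 1x1 network has no
    freedom and returns 0.
    """
    a = np.asarray(_counts(net), dtype=int)
    if a.sum() < 1:
        raise ValueError("empty network")
    if a.shape == (1, 1):
        return 0.0
    rows = tuple(sorted(int(x) for x in a.sum(axis=1)))
    cols = tuple(sorted(int(x) for x in a.sum(axis=0)))
    if len(cols) < len(rows):  # extremes are transpose-symmetric; small side first
        rows, cols = cols, rows
    hmin, hmax = _entropy_bounds(rows, cols)
    if hmax - hmin <= 1e-12:
        return 0.0
    h2 = _matrix_entropy(a)
    return float(min(1.0, max(0.0, (hmax - h2) / (hmax - hmin))))


# ------------------------------------------------------------------- d'

def _kl(counts: np.ndarray, q: np.ndarray) -> float:
    tot = counts.sum()
    mask = counts > 0
    p = counts[mask] / tot
    return float((p * np.log(p / q[mask])).sum())


def _dmin_exact(total: int, q: np.ndarray) -> float:
    """Exact minimum KL divergence over integer allocations of `total` visits.

    The objective is separable and convex in each allocation, so incremental
    greedy allocation by smallest marginal cost is provably optimal.
    """
    A = total
    logq = np.log(q)

    def f(n: int, i: int) -> float:
        return 0.0 if n == 0 else (n / A) * (math.log(n / A) - logq[i])

    heap = [(f(1, i) - 0.0, i, 0) for i in range(len(q))]
    heapq.heapify(heap)
    alloc = np.zeros(len(q), dtype=int)
    for _ in range(A):
        _, i, n = heapq.heappop(heap)
        alloc[i] = n + 1
        heapq.heappush(heap, (f(n + 2, i) - f(n + 1, i), i, n + 1))
    return _kl(alloc, q)


def _dmax_exact(total: int, caps: np.ndarray, q: np.ndarray) -> float:
    """Exact maximum KL divergence over integer allocations n_i <= caps_i.

    Max-plus dynamic programme over plants; exact because the objective is
    additive across plants given the visitor total.
    """
    A = total
    logq = np.log(q)
    neg = -math.inf
    dp = np.full(A + 1, neg)
    dp[0] = 0.0
    for i in range(len(q)):
        cap = int(min(caps[i], A))
        if cap == 0:
            continue
        ns = np.arange(1, cap + 1)
        vals = (ns / A) * (np.log(ns / A) - logq[i])
        new = dp.copy()
        for n, v in zip(ns, vals):
            shifted = np.full(A + 1, neg)
            shifted[n:] = dp[:-n] if n > 0 else dp
            np.maximum(new, shifted + v, out=new)
        dp = new
    return float(dp[A])


@lru_cache(maxsize=16384)
def _dprime_bounds(total: int, row_totals: tuple[int, ...]) -> tuple[float, float]:
    r = np.asarray(row_totals, dtype=float)
    q = r / r.sum()
    return _dmin_exact(total, q), _dmax_exact(total, r, q)


def dprime(net, j: int) -> float:
    """Standardised specialisation d' of visitor column ``j`` in [0, 1].

    Raw d is the KL divergence between the visitor's distribution of visits
    over plants and plant availability (row totals / m); it is standardised
    between the minimum and maximum divergence attainable by an integer
    visitor with the same total, given availability and plant totals.
    """
    a = np.asarray(_counts(net), dtype=int)
    col = a[:, j]
    A = int(col.sum())
    if A < 1:
        raise ValueError("visitor column has no visits")
    r = a.sum(axis=1)
    q = r / r.sum()
    d = _kl(col, q)
    dmin, dmax = _dprime_bounds(A, tuple(int(x) for x in r))
    if dmax - dmin <= 1e-12:
        return 0.0
    return float(min(1.0, max(0.0, (d - dmin) / (dmax - dmin))))


def dprime_all(net) -> np.ndarray:
    a = np.asarray(_counts(net), dtype=int)
    return np.array([dprime(a, j) for j in range(a.shape[1])])


def mean_dprime(net, weighted: bool = False) -> float:
    """Network-level visitor specialisation: mean of per-visitor d'.

    Unweighted by default (each visitor species counts once); with
    ``weighted=True`` visitors are weighted by their visit totals.
    """
    a = np.asarray(_counts(net), dtype=int)
    d = dprime_all(a)
    if weighted:
        w = a.sum(axis=0)
        return float((d * w).sum() / w.sum())
    return float(d.mean())


# ------------------------------------------------------------- modularity

@dataclass
class SAParams:
    """Simulated-annealing schedule for bipartite modularity.

    ``t0=None`` calibrates the initial temperature so that roughly half of
    uphill moves are accepted at the start.  Geometric cooling; each
    temperature level runs ``steps_per_level`` single-node reassignment
    moves (with an occasional module merge), and the chain stops after
    ``patience`` levels without improvement of the best Q.
    """

    t0: float | None = None
    cooling: float = 0.99
    steps_per_level: int | None = None
    patience: int = 40
    max_levels: int = 400
    merge_prob: float = 0.05

    def __post_init__(self):
        if not (0.0 < self.cooling < 1.0):
            raise ValueError("cooling factor must be in (0, 1)")
        if self.steps_per_level is not None and self.steps_per_level <= 0:
            raise ValueError("step budget must be positive")
        if self.max_levels <= 0 or self.patience <= 0:
            raise ValueError("step budget must be positive")


def modularity_q(net, row_labels: np.ndarray, col_labels: np.ndarray) -> float:
    """Barber weighted bipartite modularity of a given joint partition:
    Q = (1/m) * sum_ij [a_ij - r_i c_j / m] over cells whose row and column
    share a module."""
    a = np.asarray(_counts(net), dtype=float)
    m = a.sum()
    r = a.sum(axis=1)
    c = a.sum(axis=0)
    b = (a - np.outer(r, c) / m) / m
    same = np.asarray(row_labels)[:, None] == np.asarray(col_labels)[None, :]
    return float(b[same].sum())


class _SAState:
    """Joint module assignment with O(degree) incremental Q updates."""

    def __init__(self, a: np.ndarray, rng: np.random.Generator):
        self.a = a.astype(float)
        self.R, self.C = a.shape
        self.n = self.R + self.C
        self.m = a.sum()
        self.r = a.sum(axis=1)
        self.c = a.sum(axis=0)
        self.rng = rng
        nmod = self.n
        self.labels = np.arange(self.n)
        # module aggregates
        self.W = np.zeros(nmod)  # within-module interaction mass
        self.Rg = np.zeros(nmod)  # row-margin mass per module
        self.Cg = np.zeros(nmod)  # col-margin mass per module
        self.Rg[: self.R] = self.r
        self.Cg[self.R :] = self.c
        # srow[i, g] = sum of a[i, j] over columns j in module g (and sym.)
        self.srow = np.zeros((self.R, nmod))
        self.scol = np.zeros((self.C, nmod))
        for j in range(self.C):
            self.srow[:, self.R + j] = self.a[:, j]
        for i in range(self.R):
            self.scol[:, i] = self.a[i, :]
        self.q = self._q_full()

    def _q_full(self) -> float:
        return float(self.W.sum() / self.m - (self.Rg * self.Cg).sum() / self.m**2)

    def delta_move(self, node: int, dest: int) -> float:
        src = self.labels[node]
        m = self.m
        if node < self.R:
            s_src = self.srow[node, src]
            s_dst = self.srow[node, dest]
            w = self.r[node]
            return (s_dst - s_src) / m + w * (self.Cg[src] - self.Cg[dest]) / m**2
        j = node - self.R
        s_src = self.scol[j, src]
        s_dst = self.scol[j, dest]
        w = self.c[j]
        return (s_dst - s_src) / m + w * (self.Rg[src] - self.Rg[dest]) / m**2

    def apply_move(self, node: int, dest: int, dq: float) -> None:
        src = self.labels[node]
        if node < self.R:
            self.W[src] -= self.srow[node, src]
            self.W[dest] += self.srow[node, dest]
            self.Rg[src] -= self.r[node]
            self.Rg[dest] += self.r[node]
            self.scol[:, src] -= self.a[node, :]
            self.scol[:, dest] += self.a[node, :]
        else:
            j = node - self.R
            self.W[src] -= self.scol[j, src]
            self.W[dest] += self.scol[j, dest]
            self.Cg[src] -= self.c[j]
            self.Cg[dest] += self.c[j]
            self.srow[:, src] -= self.a[:, j]
            self.srow[:, dest] += self.a[:, j]
        self.labels[node] = dest
        self.q += dq

    def delta_merge(self, g: int, h: int) -> float:
        rows_g = self.labels[: self.R] == g
        rows_h = self.labels[: self.R] == h
        cross = self.srow[rows_g, h].sum() + self.srow[rows_h, g].sum()
        return cross / self.m - (
            self.Rg[g] * self.Cg[h] + self.Rg[h] * self.Cg[g]
        ) / self.m**2

    def apply_merge(self, g: int, h: int, dq: float) -> None:
        rows_g = self.labels[: self.R] == g
        rows_h = self.labels[: self.R] == h
        cross = self.srow[rows_g, h].sum() + self.srow[rows_h, g].sum()
        self.labels[self.labels == h] = g
        self.W[g] += self.W[h] + cross
        self.W[h] = 0.0
        self.Rg[g] += self.Rg[h]
        self.Cg[g] += self.Cg[h]
        self.Rg[h] = 0.0
        self.Cg[h] = 0.0
        self.srow[:, g] += self.srow[:, h]
        self.srow[:, h] = 0.0
        self.scol[:, g] += self.scol[:, h]
        self.scol[:, h] = 0.0
        self.q += dq


def _anneal(a: np.ndarray, params: SAParams, rng: np.random.Generator):
    st = _SAState(a, rng)
    n = st.n
    steps = params.steps_per_level or 2 * n
    # temperature calibration: aim for ~50% acceptance of uphill moves
    if params.t0 is None:
        probes = []
        for _ in range(min(100, 10 * n)):
            node = int(rng.integers(n))
            dest = int(rng.integers(n))
            if dest != st.labels[node]:
                dq = st.delta_move(node, dest)
                if dq < 0:
                    probes.append(-dq)
        t = (float(np.mean(probes)) / math.log(2.0)) if probes else 1e-3
    else:
        t = params.t0
    best_q = st.q
    best_labels = st.labels.copy()
    stale = 0
    for _ in range(params.max_levels):
        improved = False
        for _ in range(steps):
            if rng.random() < params.merge_prob:
                mods = np.unique(st.labels)
                if len(mods) > 1:
                    g, h = rng.choice(mods, size=2, replace=False)
                    dq = st.delta_merge(int(g), int(h))
                    if dq >= 0 or rng.random() < math.exp(dq / t):
                        st.apply_merge(int(g), int(h), dq)
            else:
                node = int(rng.integers(n))
                dest = int(rng.integers(n))
                if dest == st.labels[node]:
                    continue
                dq = st.delta_move(node, dest)
                if dq >= 0 or rng.random() < math.exp(dq / t):
                    st.apply_move(node, dest, dq)
            if st.q > best_q + 1e-12:
                best_q = st.q
                best_labels = st.labels.copy()
                improved = True
        stale = 0 if improved else stale + 1
        if stale >= params.patience:
            break
        t *= params.cooling
    return best_q, best_labels


def modularity(
    net,
    sa_params: SAParams | None = None,
    seed: int | np.random.Generator = 0,
    n_restarts: int = 3,
) -> tuple[float, dict[str, np.ndarray]]:
    """Maximise Barber quantitative bipartite modularity by simulated
    annealing (QuanBiMo-style single-node reassignments plus module merges).

    Returns the best Q found over ``n_restarts`` seeded chains and the
    corresponding partition as ``{"rows": labels, "cols": labels}`` with
    consecutive module ids.  Deterministic for a given seed and parameters.
    """
    a = np.asarray(_counts(net), dtype=float)
    if a.sum() < 2:
        raise ValueError("modularity requires at least 2 interactions")
    params = sa_params or SAParams()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    best_q, best_labels = -math.inf, None
    for _ in range(max(1, n_restarts)):
        q, labels = _anneal(a, params, rng)
        if q > best_q:
            best_q, best_labels = q, labels
    R = a.shape[0]
    # exact Q of the returned partition, recomputed from the definition
    q_exact = modularity_q(a, best_labels[:R], best_labels[R:])
    _, relab = np.unique(best_labels, return_inverse=True)
    return q_exact, {"rows": relab[:R], "cols": relab[R:]}
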