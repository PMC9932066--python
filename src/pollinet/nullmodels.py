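"""Fixed-margin null models and the Delta-standardisation of network metrics.

Network metrics depend strongly on network size and sampling intensity, so
observed values are standardised against random interaction matrices with
exactly the observed row and column totals (Patefield's algorithm, i.e. the
independence-conditional multiple hypergeometric distribution).  The
Delta-transformation reports ``observed - mean(null)``: how far a metric
departs from random expectation at fixed margins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from . import netmetrics
from .netbuild import BipartiteNetwork
from .netmetrics import SAParams

log = logging.getLogger(__name__)

#: draws used per metric unless overridden; modularity uses fewer because
#: each draw requires a full annealing run.
DEFAULT_N_NULL = 1000
DEFAULT_N_NULL_MODULARITY = 100

METRICS: dict[str, Callable] = {
    "connectance": netmetrics.connectance,
    "nodf": netmetrics.nodf,
    "h2prime": netmetrics.h2prime,
    "mean_dprime": netmetrics.mean_dprime,
}


def patefield_sample(
    row_totals, col_totals, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """One random integer table with exactly the given margins.

    Sampled from the distribution of tables under row/column independence
    (multiple hypergeometric), via sequential conditional sampling.
    """
    r = np.asarray(row_totals, dtype=int)
    c = np.asarray(col_totals, dtype=int)
    if r.sum() != c.sum():
        raise ValueError(
            f"margin sums differ: rows {int(r.sum())} vs cols {int(c.sum())}"
        )
    if r.sum() < 1:
        raise ValueError("margins must sum to at least 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    # a single row or column admits exactly one table
    if len(r) == 1:
        return c.reshape(1, -1).copy()
    if len(c) == 1:
        return r.reshape(-1, 1).copy()
    return stats.random_table(r, c).rvs(method="patefield", random_state=rng).astype(int)


@dataclass(frozen=True)
class DeltaResult:
    """Observed metric, its null distribution summary, and Delta."""

    metric: str
    observed: float
    null_mean: float
    null_sd: float
    n_null: int
    n_rejected: int = 0

    @property
    def delta(self) -> float:
        return self.observed - self.null_mean


def delta_transform(
    net: BipartiteNetwork | np.ndarray,
    metric: str | Callable,
    n_null: int | None = None,
    rng: np.random.Generator | int | None = None,
    sa_params: SAParams | None = None,
    null_restarts: int = 1,
) -> DeltaResult:
    """Delta-standardise one metric against Patefield null draws.

    ``metric`` is a metric name (``connectance``, ``nodf``, ``h2prime``,
    ``mean_dprime``, ``modularity``) or any callable on a count matrix.
    Defaults to 1000 null draws, 100 for modularity.  Null modularity runs a
    single annealing restart per draw (budget-matched to the observed fit's
    per-restart effort); draws on which the metric is undefined are rejected
    and resampled, with a logged count.
    """
    a = net.counts if isinstance(net, BipartiteNetwork) else np.asarray(net, dtype=int)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    if callable(metric):
        name = getattr(metric, "__name__", "custom")
        fn = metric
    elif metric == "modularity":
        name = "modularity"

        def fn(x, _params=sa_params, _rng=rng):
            q, _ = netmetrics.modularity(
                x, sa_params=_params, seed=_rng, n_restarts=null_restarts
            )
            return q

    elif metric in METRICS:
        name = metric
        fn = METRICS[metric]
    else:
        raise KeyError(f"unknown metric {metric!r}")

    if n_null is None:
        n_null = DEFAULT_N_NULL_MODULARITY if name == "modularity" else DEFAULT_N_NULL
    if n_null < 1:
        raise ValueError("n_null must be >= 1")

    if name == "modularity":
        observed, _ = netmetrics.modularity(a, sa_params=sa_params, seed=rng)
    else:
        observed = float(fn(a))

    r = a.sum(axis=1)
    c = a.sum(axis=0)
    vals = np.empty(n_null)
    rejected = 0
    i = 0
    while i < n_null:
        draw = patefield_sample(r, c, rng)
        try:
            vals[i] = float(fn(draw))
        except (ValueError, ZeroDivisionError):
            rejected += 1
            if rejected > 100 * n_null:
                raise RuntimeError(
                    f"metric {name} undefined on too many null draws"
                )
            continue
        i += 1
    if rejected:
        log.info("delta_transform(%s): %d null draws rejected", name, rejected)
    return DeltaResult(
        metric=name,
        observed=observed,
        null_mean=float(vals.mean()),
        null_sd=float(vals.std(ddof=1)) if n_null > 1 else 0.0,
        n_null=n_null,
        n_rejected=rejected,
    )


def delta_suite(
    net,
    n_null: int = DEFAULT_N_NULL,
    n_null_modularity: int = DEFAULT_N_NULL_MODULARITY,
    rng: np.random.Generator | int | None = None,
    sa_params: SAParams | None = None,
) -> dict[str, DeltaResult]:
    """Delta-transform all five metrics of one network."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = {}
    for name in METRICS:
        out[name] = delta_transform(net, name, n_null=n_null, rng=rng)
    out["modularity"] = delta_transform(
        net, "modularity", n_null=n_null_modularity, rng=rng, sa_params=sa_params
    )
    return out
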