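"""Community diversity summaries and composition-analysis preprocessing.

Composition analysis follows the standard vegan-style chain: rare visitors
filtered (>= 3 visits across sites), square-root transform, Wisconsin double
standardisation, Bray-Curtis dissimilarity, a 2-D ordination (supplied
externally or by principal-coordinate analysis), and permutation-based
fitting of environmental vectors onto the ordination.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .netbuild import filter_min_visits, validate_records


def shannon(counts) -> float:
    """Shannon diversity H = -sum p ln p (nats) of a count vector."""
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("Shannon diversity undefined for all-zero counts")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def site_summaries(records: pd.DataFrame) -> pd.DataFrame:
    """Per site and visitor group: visitation rate (pooled visits), species
    richness and Shannon diversity of visit counts."""
    rec = validate_records(records)
    rows = []
    for (site, group), sub in rec.groupby(["site_id", "visitor_group"]):
        by_sp = sub.groupby("visitor_species")["count"].sum()
        rows.append(
            {
                "site_id": site,
                "visitor_group": group,
                "visits": int(by_sp.sum()),
                "richness": int((by_sp > 0).sum()),
                "shannon": shannon(by_sp.to_numpy()),
            }
        )
    return pd.DataFrame(rows)


def site_by_species(
    records: pd.DataFrame, min_visits: int = 3
) -> pd.DataFrame:
    """Site x visitor-species count table, rare species filtered."""
    rec = filter_min_visits(records, min_visits) if min_visits > 1 else validate_records(records)
    if rec.empty:
        raise ValueError("no records left after filtering")
    return (
        rec.pivot_table(
            index="site_id",
            columns="visitor_species",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        .sort_index(axis=0)
        .sort_index(axis=1)
    )


def wisconsin(mat: pd.DataFrame) -> pd.DataFrame:
    """Wisconsin double standardisation: columns to their maxima, then rows
    to their totals."""
    out = mat / mat.max(axis=0)
    out = out.div(out.sum(axis=1), axis=0)
    return out


def braycurtis_prepared(comm: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarities after square-root transform and Wisconsin
    double standardisation (the metaMDS-style default chain).

    ``comm`` is a site x species count table whose species have already
    passed the minimum-visit filter.  Errors on a site whose row total is
    zero, naming the site.
    """
    if comm.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    zero = comm.index[comm.sum(axis=1) == 0].tolist()
    if zero:
        raise ValueError(f"sites with zero total counts: {zero}")
    prep = wisconsin(np.sqrt(comm.astype(float)))
    d = squareform(pdist(prep.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(d, index=comm.index, columns=comm.index)


def envfit_permutation(
    coords: np.ndarray | pd.DataFrame,
    env: np.ndarray | pd.Series,
    n_perm: int = 99_999,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Fit one environmental vector onto 2-D ordination coordinates.

    R^2 is the squared multiple correlation of the variable regressed on the
    two ordination axes; significance comes from permuting the variable over
    sites, with the add-one estimator
    ``p = (1 + #{perm R^2 >= observed}) / (1 + n_perm)`` so p is never zero.
    """
    X = np.asarray(coords, dtype=float)
    y = np.asarray(env, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("coords must be (n_sites, k) aligned with env")
    if np.std(y) == 0:
        raise ValueError("environmental variable is constant")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    Xc = X - X.mean(axis=0)
    hat = Xc @ np.linalg.pinv(Xc)  # projection onto the ordination axes

    def r2(yy: np.ndarray) -> float:
        yc = yy - yy.mean()
        return float(yc @ hat @ yc) / float(yc @ yc)

    observed = r2(y)
    hits = 0
    for _ in range(n_perm):
        if r2(rng.permutation(y)) >= observed - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return observed, p
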