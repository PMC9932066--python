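"""Quantitative bipartite networks from flower-visitation records.

Interaction records are long-format rows (site, sampling round, plant
species, visitor species, visitor group, visit count).  A network pools all
rounds of one site into a plant x visitor count matrix.  Visitor columns can
be aggregated from species to genus resolution; plants always stay at
species resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VISITOR_GROUPS = ("wild_bee", "hoverfly", "butterfly", "honey_bee")
#: groups counted as wild pollinators in summaries (honey bees are managed)
WILD_GROUPS = ("wild_bee", "hoverfly", "butterfly")

RECORD_COLUMNS = (
    "site_id",
    "round",
    "plant_species",
    "visitor_species",
    "visitor_group",
    "count",
)


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format record table and return it with canonical dtypes."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"record table missing columns: {missing}")
    rec = records.loc[:, list(RECORD_COLUMNS)].copy()
    counts = pd.to_numeric(rec["count"])
    if (counts < 1).any() or not np.allclose(counts, counts.astype(int)):
        raise ValueError("visit counts must be positive integers")
    rec["count"] = counts.astype(int)
    bad = set(rec["visitor_group"]) - set(VISITOR_GROUPS)
    if bad:
        raise ValueError(f"unknown visitor groups: {sorted(bad)}")
    return rec


@dataclass(frozen=True)
class BipartiteNetwork:
    """Quantitative plant x visitor interaction matrix for one site.

    Rows are plant species, columns visitor taxa; ``counts[i, j]`` is the
    number of recorded visits.  Labels are kept sorted so matrices are
    canonical.  Rows/columns with zero total are never stored.
    """

    counts: np.ndarray
    plants: tuple[str, ...]
    visitors: tuple[str, ...]
    site_id: str
    resolution: str = "species"
    visitor_groups: tuple[str, ...] = field(default=())

    def __post_init__(self):
        a = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", a)
        if a.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if a.shape != (len(self.plants), len(self.visitors)):
            raise ValueError("label lengths do not match matrix shape")
        if (a < 0).any():
            raise ValueError("counts must be nonnegative")
        if a.sum() < 1:
            raise ValueError("network must contain at least one interaction")
        if (a.sum(axis=1) == 0).any() or (a.sum(axis=0) == 0).any():
            raise ValueError("all-zero rows/columns are not allowed")
        if len(set(self.plants)) != len(self.plants) or len(
            set(self.visitors)
        ) != len(self.visitors):
            raise ValueError("labels must be unique")

    @property
    def m(self) -> int:
        """Total number of interactions."""
        return int(self.counts.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.plants), columns=list(self.visitors)
        )

    def with_counts(self, counts: np.ndarray) -> "BipartiteNetwork":
        """Same labels, new matrix (used for null-model draws)."""
        return replace(self, counts=np.asarray(counts, dtype=int))


def build_network(
    records: pd.DataFrame,
    site_id: str,
    *,
    include_honey_bees: bool = True,
) -> BipartiteNetwork:
    """Pool all sampling rounds of one site into a quantitative network.

    ``a_ij`` is the sum of visit counts over rounds for (plant i, visitor j).
    Honey bees are network members by default but can be excluded for
    wild-pollinator-only networks.
    """
    rec = validate_records(records)
    rec = rec[rec["site_id"] == site_id]
    if not include_honey_bees:
        rec = rec[rec["visitor_group"] != "honey_bee"]
    if rec.empty:
        raise ValueError(f"no records for site {site_id!r}")
    mat = (
        rec.pivot_table(
            index="plant_species",
            columns="visitor_species",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    groups = (
        rec.drop_duplicates("visitor_species")
        .set_index("visitor_species")["visitor_group"]
        .reindex(mat.columns)
    )
    return BipartiteNetwork(
        counts=mat.to_numpy(dtype=int),
        plants=tuple(mat.index),
        visitors=tuple(mat.columns),
        site_id=site_id,
        resolution="species",
        visitor_groups=tuple(groups),
    )


def genus_map_from_labels(labels: Iterable[str]) -> dict[str, str]:
    """Taxonomy map taking the genus as the first whitespace token."""
    out = {}
    for lab in labels:
        genus = lab.split()[0]
        if not genus:
            raise ValueError(f"cannot derive genus from label {lab!r}")
        out[lab] = genus
    return out


def aggregate_to_genus(
    net: BipartiteNetwork, taxonomy: Mapping[str, str] | None = None
) -> BipartiteNetwork:
    """Sum visitor columns sharing a genus; plant rows are unchanged.

    The total number of interactions m is preserved.  With ``taxonomy=None``
    the genus is taken as the first token of each visitor label.
    """
    if taxonomy is None:
        taxonomy = genus_map_from_labels(net.visitors)
    missing = [v for v in net.visitors if v not in taxonomy]
    if missing:
        raise KeyError(f"no genus mapping for visitor species: {missing}")
    genera = sorted({taxonomy[v] for v in net.visitors})
    idx = {g: k for k, g in enumerate(genera)}
    agg = np.zeros((len(net.plants), len(genera)), dtype=int)
    groups: dict[str, str] = {}
    for j, v in enumerate(net.visitors):
        g = taxonomy[v]
        agg[:, idx[g]] += net.counts[:, j]
        if net.visitor_groups:
            groups.setdefault(g, net.visitor_groups[j])
    return BipartiteNetwork(
        counts=agg,
        plants=net.plants,
        visitors=tuple(genera),
        site_id=net.site_id,
        resolution="genus",
        visitor_groups=tuple(groups[g] for g in genera) if groups else (),
    )


def filter_min_visits(records: pd.DataFrame, k: int = 3) -> pd.DataFrame:
    """Drop visitor species with fewer than ``k`` visits summed over all sites.

    Used before community-composition analysis to remove statistical noise
    from rarely observed visitors; the conventional threshold is 3.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rec = validate_records(records)
    totals = rec.groupby("visitor_species")["count"].sum()
    keep = set(totals.index[totals >= k])
    return rec[rec["visitor_species"].isin(keep)].reset_index(drop=True)


# ---------------------------------------------------------------- file I/O

def read_records(path: str | Path) -> pd.DataFrame:
    return validate_records(pd.read_csv(path, sep="\t"))


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    validate_records(records).to_csv(path, sep="\t", index=False)


def write_matrix(net: BipartiteNetwork, path: str | Path) -> None:
    """Labelled TSV, plants as rows and visitor taxa as columns."""
    net.to_frame().to_csv(path, sep="\t", index_label="plant_species")


def read_matrix(
    path: str | Path, site_id: str = "", resolution: str = "species"
) -> BipartiteNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return BipartiteNetwork(
        counts=df.to_numpy(dtype=int),
        plants=tuple(df.index),
        visitors=tuple(df.columns),
        site_id=site_id or Path(path).stem,
        resolution=resolution,
    )
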