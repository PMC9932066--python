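"""Synthetic landscapes, floral communities and visitation records.

The generator emulates the design of an urban dry-grassland pollination
study: 11 grassland patches on an urbanisation gradient, impervious-surface
percentages measured at 100/500/1000 m buffers (correlated across radii
through a shared latent gradient), a pool of ~105 wild bee, ~38 hoverfly and
~22 butterfly species plus honey bees visiting ~60 flowering plant species
over 8 sampling rounds per season.

Group-specific responses mirror the qualitative structure such studies
report: wild bee richness declines log-linearly with impervious surface at
the 500 m radius and butterfly richness at 100 m, hoverflies are
unresponsive to urbanisation, honey-bee visits and flower abundance increase
with it, and hoverfly/butterfly visitation rates increase with vegetation
height.  Plant-visitor pairing follows latent trait matching: one trait per
species on [0, 1], pairing weight proportional to
``exp(-specialisation_strength * |trait difference|)``, which moves network
specialisation smoothly from fully generalised to highly specialised.

Effect sizes are free parameters of the generator (log-scale slopes per
standard deviation of the covariate), not estimates of any particular field
study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .netbuild import RECORD_COLUMNS

BEE_GENERA = (
    "Andrena", "Lasioglossum", "Bombus", "Halictus", "Colletes", "Hylaeus",
    "Megachile", "Osmia", "Nomada", "Anthidium", "Melitta", "Eucera",
    "Anthophora", "Sphecodes", "Dasypoda",
)
HOVERFLY_GENERA = (
    "Eristalis", "Syrphus", "Sphaerophoria", "Episyrphus", "Helophilus",
    "Syritta", "Melanostoma", "Paragus", "Cheilosia", "Myathropa",
)
BUTTERFLY_GENERA = (
    "Pieris", "Polyommatus", "Thymelicus", "Argynnis", "Lycaena", "Maniola",
    "Coenonympha", "Vanessa",
)
PLANT_GENERA = (
    "Berteroa", "Medicago", "Trifolium", "Achillea", "Centaurea", "Daucus",
    "Echium", "Hypericum", "Potentilla", "Silene", "Crepis", "Knautia",
)


def _default_pool_sizes() -> dict[str, int]:
    return {"wild_bee": 105, "hoverfly": 38, "butterfly": 22, "plant": 60}


def _default_effect_sizes() -> dict[str, float]:
    # log-scale slopes per SD of the named covariate
    return {
        "bee_richness_vs_impervious": -0.5,     # at the 500 m radius
        "butterfly_richness_vs_impervious": -0.6,  # at the 100 m radius
        "hoverfly_richness_vs_impervious": 0.0,
        "honey_bee_visits_vs_impervious": 0.7,  # at the 100 m radius
        "flower_abundance_vs_impervious": 0.4,  # at the 1000 m radius
        "visits_vs_vegheight": 0.3,             # hoverflies and butterflies
    }


@dataclass
class SyntheticConfig:
    """Parameters governing the synthetic study design."""

    n_sites: int = 11
    seed: int = 0
    impervious_range: tuple[float, float] = (5.0, 75.0)
    cross_scale_corr: float = 0.7
    patch_size_range: tuple[float, float] = (2_000.0, 100_000.0)
    n_buildings_per_site: int = 40
    height_range: tuple[float, float] = (4.0, 30.0)
    pool_sizes: dict[str, int] = field(default_factory=_default_pool_sizes)
    effect_sizes: dict[str, float] = field(default_factory=_default_effect_sizes)
    specialisation_strength: float = 6.0
    sampling_rounds: int = 8
    #: expected visits per present wild visitor species
    mean_visits_per_species: float = 5.0
    #: negative-binomial size parameter for visit counts ("poisson" uses
    #: Poisson counts instead)
    count_family: str = "negative_binomial"
    nb_size: float = 1.5
    extent_m: float = 12_000.0

    def __post_init__(self):
        for name, rng_ in (
            ("impervious_range", self.impervious_range),
            ("patch_size_range", self.patch_size_range),
            ("height_range", self.height_range),
        ):
            if not rng_[0] < rng_[1]:
                raise ValueError(f"{name} must be a non-degenerate interval")
        if not 0.0 <= self.cross_scale_corr <= 1.0:
            raise ValueError("cross_scale_corr must be in [0, 1]")
        if any(v < 1 for v in self.pool_sizes.values()):
            raise ValueError("pool sizes must be >= 1")
        if self.specialisation_strength < 0:
            raise ValueError("specialisation_strength must be nonnegative")
        if self.sampling_rounds < 1 or self.n_sites < 1:
            raise ValueError("counts must be >= 1")
        if self.count_family not in ("negative_binomial", "poisson"):
            raise ValueError("count_family must be negative_binomial or poisson")


@dataclass
class Landscape:
    """Per-site geometry and urbanisation covariates.

    ``sites``: indexed by site id with columns x, y (m), area_m2 and
    impervious percentages at the three radii.  ``buildings``: x, y,
    height_m.  ``distances``: symmetric centroid-to-centroid matrix (m).
    """

    sites: pd.DataFrame
    buildings: pd.DataFrame
    distances: pd.DataFrame

    def __post_init__(self):
        imp = self.sites[["imperv_100", "imperv_500", "imperv_1000"]].to_numpy()
        if ((imp < 0) | (imp > 100)).any():
            raise ValueError("impervious percentages must lie in [0, 100]")
        if (self.sites["area_m2"] <= 0).any():
            raise ValueError("patch areas must be positive")
        if (self.buildings["height_m"] < 0).any():
            raise ValueError("building heights must be nonnegative")
        d = self.distances.to_numpy()
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites.index)


def generate_landscape(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> Landscape:
    """Generate site geometry and impervious-surface covariates.

    Impervious percentages at the three radii share a latent urbanisation
    gradient: each is ``sqrt(rho) * gradient + sqrt(1-rho) * noise`` mapped
    linearly onto the configured range, so every pair of radii has
    correlation ~``cross_scale_corr``.  Deterministic given the config seed.
    """
    if config.n_sites < 2:
        raise ValueError("need at least 2 sites for pairwise distances")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_sites
    ids = [f"site_{i+1:02d}" for i in range(n)]

    rho = config.cross_scale_corr
    latent = rng.normal(size=n)
    z = np.sqrt(rho) * latent[:, None] + np.sqrt(1.0 - rho) * rng.normal(size=(n, 3))
    lo, hi = config.impervious_range
    center, scale = (lo + hi) / 2.0, (hi - lo) / 6.0
    imperv = np.clip(center + scale * z, 0.0, 100.0)

    xy = rng.uniform(0.0, config.extent_m, size=(n, 2))
    log_lo, log_hi = np.log(config.patch_size_range)
    areas = np.exp(rng.uniform(log_lo, log_hi, size=n))

    sites = pd.DataFrame(
        {
            "x": xy[:, 0],
            "y": xy[:, 1],
            "area_m2": areas,
            "imperv_100": imperv[:, 0],
            "imperv_500": imperv[:, 1],
            "imperv_1000": imperv[:, 2],
        },
        index=pd.Index(ids, name="site_id"),
    )

    bxs, bys, bhs = [], [], []
    for i in range(n):
        bx = rng.uniform(xy[i, 0] - 600.0, xy[i, 0] + 600.0, config.n_buildings_per_site)
        by = rng.uniform(xy[i, 1] - 600.0, xy[i, 1] + 600.0, config.n_buildings_per_site)
        bh = rng.uniform(*config.height_range, config.n_buildings_per_site)
        bxs.append(bx)
        bys.append(by)
        bhs.append(bh)
    buildings = pd.DataFrame(
        {
            "x": np.concatenate(bxs),
            "y": np.concatenate(bys),
            "height_m": np.concatenate(bhs),
        }
    )

    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    distances = pd.DataFrame(d, index=sites.index, columns=sites.index)
    return Landscape(sites=sites, buildings=buildings, distances=distances)


def _species_pool(genera: tuple[str, ...], n: int, rng) -> list[str]:
    gidx = rng.integers(len(genera), size=n)
    return [f"{genera[g]} sp{k+1:03d}" for k, g in enumerate(gidx)]


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _draw_counts(mean, rng, config) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if config.count_family == "poisson":
        return rng.poisson(mean)
    k = config.nb_size
    return rng.negative_binomial(k, k / (k + mean))


def generate_visits(
    landscape: Landscape,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate visitation records and site predictors on a landscape.

    Returns ``(records, predictors)``: long-format interaction records (one
    row per site/round/plant/visitor with a positive visit count) and the
    per-site environmental predictor table.  Every present visitor species
    contributes at least one visit, so per-site richness follows its
    configured log-linear model exactly.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    eff = config.effect_sizes
    pools = config.pool_sizes
    if min(pools.values()) < 1:
        raise ValueError("species pools must be non-empty")

    plants = sorted(_species_pool(PLANT_GENERA, pools["plant"], rng))
    visitor_pools = {
        "wild_bee": sorted(_species_pool(BEE_GENERA, pools["wild_bee"], rng)),
        "hoverfly": sorted(_species_pool(HOVERFLY_GENERA, pools["hoverfly"], rng)),
        "butterfly": sorted(_species_pool(BUTTERFLY_GENERA, pools["butterfly"], rng)),
    }
    plant_traits = dict(zip(plants, rng.uniform(size=len(plants))))
    visitor_traits = {
        sp: t
        for pool in visitor_pools.values()
        for sp, t in zip(pool, rng.uniform(size=len(pool)))
    }
    visitor_traits["Apis mellifera"] = rng.uniform()

    sites = landscape.sites
    z100 = _standardise(sites["imperv_100"].to_numpy())
    z500 = _standardise(sites["imperv_500"].to_numpy())
    z1000 = _standardise(sites["imperv_1000"].to_numpy())

    veg = np.clip(rng.normal(60.0, 15.0, len(sites)), 10.0, None)
    zveg = _standardise(veg)
    bare = np.clip(5.0 + 0.30 * sites["imperv_100"].to_numpy() + rng.normal(0, 2.0, len(sites)), 0.0, 100.0)
    flower_units = rng.poisson(
        np.exp(np.log(300.0) + eff["flower_abundance_vs_impervious"] * z1000)
    )

    base_rich = {"wild_bee": 22.0, "hoverfly": 9.0, "butterfly": 6.0}
    slope = {
        "wild_bee": (eff["bee_richness_vs_impervious"], z500),
        "hoverfly": (eff["hoverfly_richness_vs_impervious"], z100),
        "butterfly": (eff["butterfly_richness_vs_impervious"], z100),
    }
    veg_effect_groups = ("hoverfly", "butterfly")

    records: list[tuple] = []
    plant_rich = np.zeros(len(sites), dtype=int)
    hb_visits = np.zeros(len(sites), dtype=int)

    for s, site_id in enumerate(sites.index):
        # local flowering community: a subset of the plant pool with
        # lognormal abundance weights
        n_pl = int(min(len(plants), max(5, rng.poisson(25))))
        plant_rich[s] = n_pl
        site_plants = sorted(rng.choice(plants, size=n_pl, replace=False))
        abund = rng.lognormal(0.0, 1.0, size=n_pl)
        pt = np.array([plant_traits[p] for p in site_plants])

        def emit(species: str, group: str, total: int) -> None:
            tv = visitor_traits[species]
            w = abund * np.exp(-config.specialisation_strength * np.abs(tv - pt))
            alloc = rng.multinomial(total, w / w.sum())
            for p_i, n_vis in enumerate(alloc):
                if n_vis == 0:
                    continue
                by_round = rng.multinomial(
                    n_vis, np.full(config.sampling_rounds, 1.0 / config.sampling_rounds)
                )
                for r_i, c in enumerate(by_round):
                    if c > 0:
                        records.append(
                            (site_id, f"r{r_i+1}", site_plants[p_i], species, group, int(c))
                        )

        for group, pool in visitor_pools.items():
            b, zcov = slope[group]
            mu = np.exp(np.log(base_rich[group]) + b * zcov[s])
            rich = int(max(1, min(len(pool), rng.poisson(mu))))
            present = rng.choice(pool, size=rich, replace=False)
            mu_visits = config.mean_visits_per_species
            if group in veg_effect_groups:
                mu_visits = mu_visits * np.exp(eff["visits_vs_vegheight"] * zveg[s])
            totals = 1 + _draw_counts(np.full(rich, mu_visits), rng, config)
            for sp, tot in zip(sorted(present), totals):
                emit(sp, group, int(tot))

        hb = int(
            _draw_counts(
                np.exp(np.log(40.0) + eff["honey_bee_visits_vs_impervious"] * z100[s]),
                rng,
                config,
            )
        )
        hb_visits[s] = hb
        if hb > 0:
            emit("Apis mellifera", "honey_bee", hb)

    rec = pd.DataFrame(records, columns=list(RECORD_COLUMNS))
    predictors = pd.DataFrame(
        {
            "imperv_100": sites["imperv_100"],
            "imperv_500": sites["imperv_500"],
            "imperv_1000": sites["imperv_1000"],
            "area_m2": sites["area_m2"],
            "log_patch_size": np.log(sites["area_m2"]),
            "flowering_plant_richness": plant_rich,
            "flower_units": flower_units,
            "veg_height": veg,
            "bare_soil": bare,
            "honey_bee_visits": hb_visits,
        },
        index=sites.index,
    )
    return rec, predictors


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[Landscape, pd.DataFrame, pd.DataFrame]:
    """Landscape + records + predictors in one seeded call."""
    landscape = generate_landscape(config)
    records, predictors = generate_visits(landscape, config)
    return landscape, records, predictors


# ---------------------------------------------------------------- file I/O

def write_dataset(
    outdir: str | Path,
    landscape: Landscape,
    records: pd.DataFrame,
    predictors: pd.DataFrame,
) -> dict[str, Path]:
    """Write all generated tables as TSV; returns the file registry."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": out / "sites.tsv",
        "buildings": out / "buildings.tsv",
        "distances": out / "distances.tsv",
        "records": out / "records.tsv",
        "predictors": out / "predictors.tsv",
    }
    landscape.sites.to_csv(paths["sites"], sep="\t")
    landscape.buildings.to_csv(paths["buildings"], sep="\t", index=False)
    landscape.distances.to_csv(paths["distances"], sep="\t")
    records.to_csv(paths["records"], sep="\t", index=False)
    predictors.to_csv(paths["predictors"], sep="\t")
    return paths
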