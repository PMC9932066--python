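"""End-to-end orchestration: generate -> build -> metrics -> null
standardisation -> connectivity/scale selection -> community composition ->
regression, as one reproducible seeded run with a manifest.

The master seed spawns fixed per-stage seeds (master + stage offset), so any
stage can be re-run in isolation and two runs with the same config produce
identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio.stats.ordination import pcoa

from . import __version__
from .community_stats import braycurtis_prepared, envfit_permutation, site_by_species, site_summaries
from .landscape import connectivity_profile, scale_table
from .netbuild import WILD_GROUPS, aggregate_to_genus, build_network, validate_records
from .netmetrics import SAParams
from .nullmodels import delta_suite
from .regression import delta_meta, fit_count_model, resolution_compare, subset_select_aic, vif_screen, attach_moran
from .synthetic_data import SyntheticConfig, generate_landscape, generate_visits

log = logging.getLogger(__name__)

STAGES = (
    "landscape",
    "visits",
    "networks",
    "delta_metrics",
    "connectivity_scale",
    "community",
    "regression",
)
#: deterministic per-stage seed offsets from the master seed
STAGE_SEED_OFFSETS = {name: 1000 + 17 * k for k, name in enumerate(STAGES)}

DELTA_METRICS = ("connectance", "nodf", "h2prime", "mean_dprime", "modularity")


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    master_seed: int
    stage_seeds: dict[str, int]
    timings: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def config_hash(config: SyntheticConfig) -> str:
    payload = yaml.safe_dump(
        {k: repr(v) for k, v in sorted(vars(config).items())}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> SyntheticConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("impervious_range", "patch_size_range", "height_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SyntheticConfig(**raw)


def _round_half_away(x: float) -> int:
    """round-half-away-from-zero, the rounding used for reported shares"""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def tally_report(records: pd.DataFrame) -> pd.DataFrame:
    """Totals and integer percentage shares of interactions and species per
    visitor group, plus the plant species count.

    Percentages are rounded half away from zero, the convention used for
    reported survey tallies.
    """
    rec = validate_records(records)
    if rec.empty:
        raise ValueError("no records")
    total = int(rec["count"].sum())
    n_species = rec.groupby("visitor_group")["visitor_species"].nunique()
    n_inter = rec.groupby("visitor_group")["count"].sum()
    all_species = int(rec["visitor_species"].nunique())
    rows = []
    for group in n_inter.index:
        rows.append(
            {
                "visitor_group": group,
                "interactions": int(n_inter[group]),
                "interactions_pct": _round_half_away(100.0 * n_inter[group] / total),
                "species": int(n_species[group]),
                "species_pct": _round_half_away(100.0 * n_species[group] / all_species),
            }
        )
    out = pd.DataFrame(rows).set_index("visitor_group")
    out.attrs["total_interactions"] = total
    out.attrs["n_visitor_species"] = all_species
    out.attrs["n_plant_species"] = int(rec["plant_species"].nunique())
    return out


def run_all(
    config: SyntheticConfig,
    outdir: str | Path | None = None,
    n_null: int = 1000,
    n_null_modularity: int = 100,
    sa_params: SAParams | None = None,
    envfit_permutations: int = 99_999,
) -> tuple[RunManifest, dict]:
    """Run the full analysis on a synthetic dataset.

    Returns the manifest and a dict of result tables: ``records``,
    ``predictors``, ``metrics`` (per site x resolution x metric, with
    observed/null mean/sd/Delta), ``scales`` (selected radius per response),
    ``connectivity``, ``community`` (envfit results), ``models`` (selected
    regression models), ``delta_tests`` and ``resolution`` comparisons.
    """
    seeds = {s: config.seed + STAGE_SEED_OFFSETS[s] for s in STAGES}
    manifest = RunManifest(
        config_hash=config_hash(config), master_seed=config.seed, stage_seeds=seeds
    )
    results: dict = {}
    t_all = time.perf_counter()

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                manifest.timings[name] = round(time.perf_counter() - self.t, 3)
                if exc is not None:
                    log.error("stage %r failed: %s", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Timer()

    with stage("landscape"):
        landscape = generate_landscape(
            config, rng=np.random.default_rng(seeds["landscape"])
        )
        results["landscape"] = landscape

    with stage("visits"):
        records, predictors = generate_visits(
            landscape, config, rng=np.random.default_rng(seeds["visits"])
        )
        results["records"] = records
        results["predictors"] = predictors

    with stage("networks"):
        nets = {}
        for site in landscape.site_ids:
            sp = build_network(records, site)
            nets[site] = {"species": sp, "genus": aggregate_to_genus(sp)}
        results["networks"] = nets

    with stage("delta_metrics"):
        rng = np.random.default_rng(seeds["delta_metrics"])
        rows = []
        for site, by_res in nets.items():
            for res_name, net in by_res.items():
                suite = delta_suite(
                    net,
                    n_null=n_null,
                    n_null_modularity=n_null_modularity,
                    rng=rng,
                    sa_params=sa_params,
                )
                for metric, dr in suite.items():
                    rows.append(
                        {
                            "site_id": site,
                            "resolution": res_name,
                            "metric": metric,
                            "observed": dr.observed,
                            "null_mean": dr.null_mean,
                            "null_sd": dr.null_sd,
                            "delta": dr.delta,
                            "n_null": dr.n_null,
                        }
                    )
        metrics = pd.DataFrame(rows)
        results["metrics"] = metrics

    with stage("connectivity_scale"):
        conn = connectivity_profile(
            landscape.sites, landscape.buildings, landscape.distances
        )
        predictors = predictors.assign(connectivity_3d=conn)
        results["predictors"] = predictors
        summaries = site_summaries(records)
        resp = {}
        for group in WILD_GROUPS:
            sub = summaries[summaries["visitor_group"] == group].set_index("site_id")
            sub = sub.reindex(landscape.site_ids).fillna(0.0)
            resp[f"{group}_richness"] = sub["richness"]
            resp[f"{group}_visits"] = sub["visits"]
        resp["honey_bee_visits"] = predictors["honey_bee_visits"]
        sp_delta = metrics[(metrics["resolution"] == "species")]
        for metric in DELTA_METRICS:
            resp[f"delta_{metric}"] = (
                sp_delta[sp_delta["metric"] == metric]
                .set_index("site_id")["delta"]
                .reindex(landscape.site_ids)
            )
        responses = pd.DataFrame(resp, index=pd.Index(landscape.site_ids, name="site_id"))
        imp = predictors[["imperv_100", "imperv_500", "imperv_1000"]].rename(
            columns=lambda c: int(c.rsplit("_", 1)[1])
        )
        scales = scale_table(responses, imp)
        results["responses"] = responses
        results["scales"] = scales
        results["connectivity"] = conn

    with stage("community"):
        rng = np.random.default_rng(seeds["community"])
        comm = site_by_species(records, min_visits=3)
        dis = braycurtis_prepared(comm)
        ord_res = pcoa(dis.to_numpy(), number_of_dimensions=2)
        coords = ord_res.samples.to_numpy()
        env_rows = []
        env_vars = [
            f"imperv_{scales.loc['wild_bee_richness', 'selected_radius']}",
            "connectivity_3d",
            "bare_soil",
            "veg_height",
        ]
        for var in env_vars:
            r2, p = envfit_permutation(
                coords,
                predictors.loc[dis.index, var],
                n_perm=envfit_permutations,
                rng=rng,
            )
            env_rows.append({"variable": var, "r2": r2, "p": p})
        results["community"] = {
            "dissimilarity": dis,
            "coordinates": pd.DataFrame(
                coords, index=dis.index, columns=["axis1", "axis2"]
            ),
            "envfit": pd.DataFrame(env_rows).set_index("variable"),
        }

    with stage("regression"):
        coords_xy = landscape.sites[["x", "y"]].to_numpy()
        models = {}
        count_responses = [
            "wild_bee_richness",
            "butterfly_richness",
            "hoverfly_visits",
            "honey_bee_visits",
        ]
        for name in count_responses:
            radius = scales.loc[name, "selected_radius"] if name in scales.index else 500
            cand_cols = [
                f"imperv_{radius}",
                "connectivity_3d",
                "log_patch_size",
                "flowering_plant_richness",
                "veg_height",
                "bare_soil",
            ]
            # the design must stay full rank: n sites > candidate count
            cand_cols = cand_cols[: max(2, len(landscape.site_ids) - 2)]
            candidates = predictors[cand_cols]
            kept, dropped = vif_screen(candidates, cutoff=3.0)
            y = responses[name].to_numpy()
            try:
                best = subset_select_aic(y, candidates[kept], response=name, family="count")
            except RuntimeError as exc:
                log.warning("model for %s skipped: %s", name, exc)
                continue
            resid = y - np.exp(
                sm_design(candidates[best.predictors]) @ best.params.to_numpy()
            )
            attach_moran(best, resid, coords_xy)
            best.ranking = None  # keep the results dict light
            models[name] = {"model": best, "vif_dropped": dropped}
        results["models"] = models

        dt_rows = []
        for res_name in ("species", "genus"):
            for metric in DELTA_METRICS:
                vals = metrics[
                    (metrics["resolution"] == res_name) & (metrics["metric"] == metric)
                ]["delta"]
                t, p = delta_meta(vals)
                dt_rows.append(
                    {
                        "resolution": res_name,
                        "metric": metric,
                        "mean_delta": float(vals.mean()),
                        "t": t,
                        "p": p,
                    }
                )
        results["delta_tests"] = pd.DataFrame(dt_rows)

        comp_rows = []
        for metric in DELTA_METRICS:
            sp = metrics[
                (metrics["resolution"] == "species") & (metrics["metric"] == metric)
            ].set_index("site_id")["delta"]
            ge = metrics[
                (metrics["resolution"] == "genus") & (metrics["metric"] == metric)
            ].set_index("site_id")["delta"]
            ge = ge.reindex(sp.index)
            comp = resolution_compare(sp, ge)
            comp_rows.append({"metric": metric, **comp})
        results["resolution"] = pd.DataFrame(comp_rows).set_index("metric")

        results["tally"] = tally_report(records)

    manifest.timings["total"] = round(time.perf_counter() - t_all, 3)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        writers = {
            "records": (records, dict(sep="\t", index=False)),
            "predictors": (predictors, dict(sep="\t")),
            "metrics": (metrics, dict(sep="\t", index=False)),
            "scales": (scales, dict(sep="\t")),
            "delta_tests": (results["delta_tests"], dict(sep="\t", index=False)),
            "resolution": (results["resolution"], dict(sep="\t")),
            "tally": (results["tally"], dict(sep="\t")),
        }
        for name, (df, kw) in writers.items():
            path = out / f"{name}.tsv"
            df.to_csv(path, **kw)
            manifest.outputs[name] = str(path)
        (out / "manifest.json").write_text(manifest.to_json())
        manifest.outputs["manifest"] = str(out / "manifest.json")

    return manifest, results


def sm_design(X: pd.DataFrame) -> np.ndarray:
    """Design matrix with intercept column, matching the fitted models."""
    arr = X.to_numpy(dtype=float)
    return np.hstack([np.ones((len(arr), 1)), arr])
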