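"""Pipeline orchestration: simulate/load -> connectivity -> turnover fits
-> prediction -> classification -> overlap -> reports.

A :class:`RunConfig` is validated up front (unknown keys rejected) before
any stage runs.  Every run directory receives the stage outputs as CSV
plus a ``manifest.json`` recording the config hash, the seed, and package
versions, so a rerun with identical config and seed reproduces all numeric
outputs.  Stages communicate only through their declared files/return
values and are independently invokable through the library API.
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

from . import __version__
from .connectivity import SpeciesParams, connectivity_vector, estimate_alpha, network_capacities
from .diagnostics import (
    default_bins,
    empirical_semivariogram,
    response_residuals,
    turnover_summary,
)
from .overlap import harmonize, overlap_counts
from .patch_io import (
    MODEL_COVARIATES,
    OccupancyTable,
    PatchNetwork,
    build_turnover_datasets,
    covariate_frame,
    load_occupancy_table,
    load_patch_table,
    suitable_patch_ids,
)
from .persistence import classify_network, results_table
from .synthetic_data import (
    SpeciesTruth,
    SyntheticConfig,
    default_truth,
    generate_network,
    simulate_occupancy,
    two_year_table,
)
from .turnover_models import (
    ModelSpec,
    all_subsets,
    averaged_table,
    model_average,
    predict_probability,
    rank_models,
    ranking_table,
    screen_quadratic_terms,
    top_model_set,
)

logger = logging.getLogger(__name__)


@dataclass
class SpeciesConfig:
    name: str
    alpha: float
    b: float = 1.0
    uses_shoreline: bool = False
    uses_broad: bool = False

    def params(self) -> SpeciesParams:
        return SpeciesParams(
            species=self.name,
            alpha=self.alpha,
            b=self.b,
            uses_shoreline=self.uses_shoreline,
            uses_broad=self.uses_broad,
        )


_KNOWN_KEYS = {
    "patches",
    "occupancy",
    "simulate",
    "species",
    "s_threshold",
    "c_threshold",
    "rescue",
    "screen_quadratics",
    "use_density",
    "seed",
    "out_dir",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Either ``patches``/``occupancy`` paths or ``simulate: true`` (synthetic
    input drawn from the seed) must be given.  ``species`` lists per-species
    dispersal parameters and habitat-use flags.
    """

    species: list[SpeciesConfig]
    patches: str | None = None
    occupancy: str | None = None
    simulate: bool = False
    s_threshold: float = 0.5
    c_threshold: float = 0.5
    rescue: bool = True
    screen_quadratics: bool = True
    use_density: bool = True
    seed: int = 0
    out_dir: str = "run"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "species" not in raw or not raw["species"]:
            raise ValueError("config must list at least one species")
        species = [
            sp if isinstance(sp, SpeciesConfig) else SpeciesConfig(**sp)
            for sp in raw["species"]
        ]
        cfg = cls(**{**raw, "species": species})
        if not cfg.simulate and (cfg.patches is None or cfg.occupancy is None):
            raise ValueError("config needs input paths or simulate: true")
        if not (0 < cfg.s_threshold < 1 and 0 < cfg.c_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        payload = {
            **{k: getattr(self, k) for k in sorted(_KNOWN_KEYS) if k != "species"},
            "species": [vars(sp) for sp in self.species],
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


GLOBAL_TERMS = tuple(t for t in MODEL_COVARIATES)


@dataclass
class SpeciesFitResult:
    species: str
    colonization_avg: object
    survival_avg: object
    colonization_rank: pd.DataFrame
    survival_rank: pd.DataFrame
    counts: object
    S_probs: pd.Series
    C_probs: pd.Series


def fit_species(
    network: PatchNetwork,
    occupancy: OccupancyTable,
    distances,
    sp_cfg: SpeciesConfig,
    screen_quadratics: bool = True,
    use_density: bool = True,
):
    """The per-species modelling stage: connectivity, turnover datasets,
    quadratic screening, all-subsets AICc ranking, top-set averaging and
    whole-network prediction."""
    params = sp_cfg.params()
    ids = suitable_patch_ids(network, params)
    caps = {pid: c for pid, c in network_capacities(network, sp_cfg.name, use_density).items()}
    occ1 = {
        pid: occupancy.get(pid, sp_cfg.name, occupancy.years[0]) or 0
        for pid in network.patch_ids
    }
    S = connectivity_vector(ids, occ1, caps, params, distances)
    conn = dict(zip(ids, S))
    cov = covariate_frame(network, ids, connectivity=conn)
    colonization, survival, counts = build_turnover_datasets(occupancy, sp_cfg.name, cov)

    results = {}
    for dataset in (colonization, survival):
        terms = list(GLOBAL_TERMS)
        if screen_quadratics:
            terms += screen_quadratic_terms(dataset)
        spec = ModelSpec(tuple(terms))
        fitted = rank_models(dataset, all_subsets(spec))
        top = top_model_set(fitted)
        avg = model_average(top)
        probs = predict_probability(avg, cov)
        results[dataset.kind] = (fitted, top, avg, probs, dataset)
    return SpeciesFitResult(
        species=sp_cfg.name,
        colonization_avg=results["colonization"][2],
        survival_avg=results["survival"][2],
        colonization_rank=ranking_table(results["colonization"][0]),
        survival_rank=ranking_table(results["survival"][0]),
        counts=counts,
        S_probs=results["survival"][3],
        C_probs=results["colonization"][3],
    ), results


def run_pipeline(config: RunConfig, out_dir=None) -> Path:
    """Execute all stages and return the run directory."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "load"
    try:
        if config.simulate:
            syn = SyntheticConfig(
                seed=config.seed,
                frac_shoreline=0.1,
                frac_broad=0.05,
                species=[
                    SpeciesTruth(species=sp.name, alpha=sp.alpha, b=sp.b,
                                 uses_shoreline=sp.uses_shoreline, uses_broad=sp.uses_broad,
                                 beta_colonization=dict(default_truth().beta_colonization),
                                 beta_survival=dict(default_truth().beta_survival))
                    for sp in config.species
                ],
                rescue=config.rescue,
            )
            network, distances = generate_network(syn)
            history, _ = simulate_occupancy(network, distances, syn)
            occupancy = two_year_table(history, syn.first_year)
        else:
            network, _ = load_patch_table(config.patches)
            occupancy = load_occupancy_table(config.occupancy)
            from .patch_io import pairwise_edge_distances

            distances = pairwise_edge_distances(
                network.coordinates(), ids=network.patch_ids
            )

        per_species_counts = {}
        per_species_maps = {}
        for sp_cfg in config.species:
            stage = f"fit:{sp_cfg.name}"
            logger.info("fitting %s", sp_cfg.name)
            fit, results = fit_species(
                network, occupancy, distances, sp_cfg,
                screen_quadratics=config.screen_quadratics,
                use_density=config.use_density,
            )
            per_species_counts[sp_cfg.name] = fit.counts
            fit.colonization_rank.to_csv(out / f"ranking_colonization_{sp_cfg.name}.csv", index=False)
            fit.survival_rank.to_csv(out / f"ranking_survival_{sp_cfg.name}.csv", index=False)
            averaged_table(fit.colonization_avg).to_csv(
                out / f"averaged_colonization_{sp_cfg.name}.csv", index=False
            )
            averaged_table(fit.survival_avg).to_csv(
                out / f"averaged_survival_{sp_cfg.name}.csv", index=False
            )

            stage = f"classify:{sp_cfg.name}"
            classified = classify_network(
                fit.S_probs.to_dict(),
                fit.C_probs.to_dict(),
                sp_cfg.name,
                config.s_threshold,
                config.c_threshold,
            )
            results_table(classified).to_csv(
                out / f"classification_{sp_cfg.name}.csv", index=False
            )
            per_species_maps[sp_cfg.name] = harmonize(
                classified, network, sp_cfg.uses_shoreline, sp_cfg.uses_broad
            )

            stage = f"diagnostics:{sp_cfg.name}"
            for kind in ("colonization", "survival"):
                _, _, _, probs, dataset = results[kind]
                pids = list(dataset.data.index)
                if len(pids) >= 2:
                    coords = np.array([[network[p].x, network[p].y] for p in pids])
                    resid = response_residuals(
                        dataset.data["y"].to_numpy(), probs.loc[pids].to_numpy()
                    )
                    sv = empirical_semivariogram(resid, coords, default_bins(coords))
                    sv.to_frame().to_csv(
                        out / f"semivariogram_{kind}_{sp_cfg.name}.csv", index=False
                    )

        stage = "overlap"
        omap = overlap_counts(per_species_maps)
        omap.to_long().to_csv(out / "overlap.csv", index=False)

        stage = "report"
        turnover_summary(per_species_counts).to_csv(out / "turnover_summary.csv", index=False)

        manifest = {
            "config_hash": config.digest(),
            "seed": config.seed,
            "version": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "outputs": sorted(p.name for p in out.glob("*.csv")),
            "elapsed_s": round(time.time() - t0, 3),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception:
        (out / "failed").write_text(f"stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise
    return out
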