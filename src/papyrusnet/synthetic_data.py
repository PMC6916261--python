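"""Synthetic patch networks and occupancy dynamics with known ground truth.

The generator emulates the structure of a fragmented wetland survey: patch
centres scattered uniformly over a square extent, lognormal areas (ha),
Beta-distributed circularity realized through the implied perimeter,
Dirichlet vegetation-condition proportions over the four categories, and a
configurable share of shoreline and broad-wetland patches with
papyrus-in-wetland containment links.

Year-to-year occupancy follows the same stochastic patch occupancy process
the turnover models estimate: an occupied patch survives with probability
invlogit(x'beta_surv); an empty patch is colonized with probability
invlogit(x'beta_col), where x contains the habitat covariates and the
incidence-function connectivity S_i computed from the *current* year's
occupancy with the species' true dispersal parameters.  In rescue mode a
population that goes extinct may be re-established by colonists within the
same year, with the patch's colonization probability.

Every stochastic call draws from substreams derived deterministically from
one explicit seed, so a configuration reproduces byte-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit

from .connectivity import SpeciesParams, connectivity_vector, network_capacities
from .patch_io import (
    HA_TO_M2,
    DistanceMatrix,
    OccupancyTable,
    Patch,
    PatchNetwork,
    pairwise_edge_distances,
    write_occupancy_table,
    write_patch_table,
)


@dataclass
class SpeciesTruth:
    """Generating parameters for one simulated species.

    Coefficient dicts are keyed by covariate name ("intercept", "area",
    "circularity", "veg_disturbed", "veg_undisturbed", "veg_mixed",
    "connectivity", optionally "<veg>^2"); missing keys mean 0.
    """

    species: str
    alpha: float
    b: float = 1.0
    beta_colonization: dict[str, float] = field(default_factory=dict)
    beta_survival: dict[str, float] = field(default_factory=dict)
    uses_shoreline: bool = False
    uses_broad: bool = False
    initial_occupancy: float = 0.5

    def params(self) -> SpeciesParams:
        return SpeciesParams(
            species=self.species,
            alpha=self.alpha,
            b=self.b,
            uses_shoreline=self.uses_shoreline,
            uses_broad=self.uses_broad,
        )


def default_truth(species: str = "sim_species") -> SpeciesTruth:
    """Study-condition defaults: hundreds of surveyed patches yield tens of
    colonizations and extinctions per year (baseline colonization ~0.2 of
    vacant patches, survival ~0.75 of occupied ones), with positive area
    and connectivity effects on colonization and a mixed-vegetation penalty
    on survival."""
    return SpeciesTruth(
        species=species,
        alpha=0.01,  # per m: mean dispersal 100 m
        beta_colonization={"intercept": -2.2, "area": 0.4, "connectivity": 0.5},
        beta_survival={"intercept": 1.0, "area": 0.5, "veg_mixed": -3.0},
        initial_occupancy=0.5,
    )


@dataclass
class SyntheticConfig:
    """Network geometry, covariate distributions and simulated dynamics."""

    n_patches: int = 500
    extent: float = 10_000.0  # square side, m
    area_mu: float = 0.0  # lognormal on ha
    area_sigma: float = 0.7
    circ_a: float = 5.0  # Beta shape for circularity
    circ_b: float = 2.0
    veg_concentration: tuple[float, float, float, float] = (2.0, 4.0, 3.0, 1.5)
    frac_shoreline: float = 0.0
    frac_broad: float = 0.0
    frac_contained: float = 0.5  # papyrus patches given a parent broad wetland
    density_sigma: float = 0.0  # lognormal per-species density; 0 = area proxy
    species: list[SpeciesTruth] = field(default_factory=lambda: [default_truth()])
    n_years: int = 2
    rescue: bool = False
    first_year: int = 2014
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patches < 2:
            raise ValueError("need at least 2 patches")
        if self.extent <= 0:
            raise ValueError("degenerate extent")
        if any(c <= 0 for c in self.veg_concentration):
            raise ValueError("Dirichlet concentrations must be positive")
        for sp in self.species:
            if not 0 <= sp.initial_occupancy <= 1:
                raise ValueError(
                    f"{sp.species}: invalid initial occupancy {sp.initial_occupancy}"
                )


def generate_network(config: SyntheticConfig) -> tuple[PatchNetwork, DistanceMatrix]:
    """Draw a patch network; distances are Euclidean between patch centres
    (the synthetic stand-in for digitized nearest-edge distances)."""
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n = config.n_patches
    xy = rng.uniform(0, config.extent, size=(n, 2))
    areas = rng.lognormal(config.area_mu, config.area_sigma, size=n)  # ha
    circ = rng.beta(config.circ_a, config.circ_b, size=n)
    circ = np.clip(circ, 1e-3, 1.0)
    perimeters = np.sqrt(4 * math.pi * areas * HA_TO_M2 / circ)
    veg = rng.dirichlet(config.veg_concentration, size=n)

    n_broad = int(round(config.frac_broad * n))
    n_shore = int(round(config.frac_shoreline * n))
    types = ["broad_wetland"] * n_broad + ["shoreline"] * n_shore
    types += ["papyrus"] * (n - len(types))
    rng.shuffle(types)

    broad_idx = [i for i, t in enumerate(types) if t == "broad_wetland"]
    parents: list[str | None] = [None] * n
    if broad_idx:
        for i, t in enumerate(types):
            if t == "papyrus" and rng.random() < config.frac_contained:
                d2 = ((xy[broad_idx] - xy[i]) ** 2).sum(axis=1)
                parents[i] = f"p{broad_idx[int(np.argmin(d2))]:04d}"

    density_draws = {}
    if config.density_sigma > 0:
        for sp in config.species:
            density_draws[sp.species] = rng.lognormal(0.0, config.density_sigma, size=n)

    patches = []
    for i in range(n):
        density = {sp: float(d[i]) for sp, d in density_draws.items()}
        patches.append(
            Patch(
                patch_id=f"p{i:04d}",
                patch_type=types[i],
                x=float(xy[i, 0]),
                y=float(xy[i, 1]),
                area=float(areas[i]),
                perimeter=float(perimeters[i]),
                veg_disturbed=float(veg[i, 0]),
                veg_moderate=float(veg[i, 1]),
                veg_undisturbed=float(veg[i, 2]),
                veg_mixed=float(veg[i, 3]),
                parent_wetland_id=parents[i],
                density=density,
            )
        )
    network = PatchNetwork(patches)
    distances = pairwise_edge_distances(xy, ids=[p.patch_id for p in patches])
    return network, distances


def _linear_predictor(
    beta: dict[str, float], cov: dict[str, np.ndarray], S: np.ndarray
) -> np.ndarray:
    lp = np.full(S.shape, beta.get("intercept", 0.0))
    for term, b in beta.items():
        if term == "intercept" or b == 0.0:
            continue
        if term == "connectivity":
            lp = lp + b * S
        elif term.endswith("^2"):
            lp = lp + b * cov[term[:-2]] ** 2
        else:
            lp = lp + b * cov[term]
    return lp


@dataclass
class SimulationLog:
    """Ground-truth event record: per species and year-pair, the sets of
    colonized / survived / extinct / vacant patch ids."""

    events: dict[str, dict[int, dict[str, list[str]]]]


def simulate_occupancy(
    network: PatchNetwork,
    distances: DistanceMatrix,
    config: SyntheticConfig,
) -> tuple[dict[tuple[str, str, int], int], SimulationLog]:
    """Simulate ``config.n_years`` years of occupancy for every species.

    Returns the full (patch, species, year) -> 0/1 history plus an event
    log tallied directly from the simulated transitions (an independent
    oracle for the turnover accounting).
    """
    ss = np.random.SeedSequence(config.seed)
    # substream 0 feeds the network; one further substream per species
    streams = ss.spawn(1 + len(config.species))[1:]
    ids = network.patch_ids
    n = len(ids)
    cov = {
        "area": np.array([network[p].area for p in ids]),
        "circularity": np.array([network[p].circularity for p in ids]),
        "veg_disturbed": np.array([network[p].veg_disturbed for p in ids]),
        "veg_undisturbed": np.array([network[p].veg_undisturbed for p in ids]),
        "veg_mixed": np.array([network[p].veg_mixed for p in ids]),
    }

    history: dict[tuple[str, str, int], int] = {}
    events: dict[str, dict[int, dict[str, list[str]]]] = {}
    for truth, stream in zip(config.species, streams):
        rng = np.random.default_rng(stream)
        params = truth.params()
        caps = network_capacities(network, truth.species)
        occ = (rng.random(n) < truth.initial_occupancy).astype(float)
        year = config.first_year
        for pid, o in zip(ids, occ):
            history[(pid, truth.species, year)] = int(o)
        events[truth.species] = {}
        for step in range(config.n_years - 1):
            occ_map = {pid: o for pid, o in zip(ids, occ)}
            S = connectivity_vector(ids, occ_map, caps, params, distances)
            p_col = expit(_linear_predictor(truth.beta_colonization, cov, S))
            p_surv = expit(_linear_predictor(truth.beta_survival, cov, S))
            u = rng.random(n)
            new = np.where(occ == 1, (u < p_surv).astype(float), (u < p_col).astype(float))
            if config.rescue:
                died = (occ == 1) & (new == 0)
                rescued = died & (rng.random(n) < p_col)
                new = np.where(rescued, 1.0, new)
            log = {"colonized": [], "survived": [], "extinct": [], "vacant": []}
            for i, pid in enumerate(ids):
                if occ[i] == 0:
                    log["colonized" if new[i] else "vacant"].append(pid)
                else:
                    log["survived" if new[i] else "extinct"].append(pid)
            events[truth.species][year + 1] = log
            occ = new
            year += 1
            for pid, o in zip(ids, occ):
                history[(pid, truth.species, year)] = int(o)
    return history, SimulationLog(events=events)


def two_year_table(
    history: dict[tuple[str, str, int], int], year1: int
) -> OccupancyTable:
    """Extract the (year1, year1+1) slice as a validated occupancy table."""
    entries = {k: v for k, v in history.items() if k[2] in (year1, year1 + 1)}
    if not entries:
        raise ValueError(f"no occupancy recorded for years {year1}, {year1 + 1}")
    return OccupancyTable(entries=entries, years=(year1, year1 + 1))


def make_two_year_dataset(
    network: PatchNetwork,
    occupancy: OccupancyTable,
    config: SyntheticConfig,
    out_dir,
) -> dict[str, str]:
    """Write the patch and occupancy CSVs in the loader's dialect, plus a
    truth JSON; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patch_path = out / "patches.csv"
    occ_path = out / "occupancy.csv"
    truth_path = out / "truth.json"
    write_patch_table(network, patch_path)
    write_occupancy_table(occupancy, occ_path)
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "config": {
                    k: v
                    for k, v in asdict(config).items()
                    if k != "species"
                },
                "species": [asdict(sp) for sp in config.species],
            },
            fh,
            indent=2,
        )
    return {
        "patches": str(patch_path),
        "occupancy": str(occ_path),
        "truth": str(truth_path),
    }
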