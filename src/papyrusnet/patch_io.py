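"""Patch-network and occupancy data model, I/O and turnover-dataset construction.

A habitat network is a set of discrete wetland patches (papyrus swamp,
shoreline fringing papyrus, or broad wetland) with geometry-derived
covariates (area in ha, circularity) and the proportions of four
vegetation-condition categories.  Occupancy is a patch x species x year
presence/absence table over exactly two consecutive survey years; from it
the two turnover datasets are built: *colonization* rows are the patches a
species was absent from in year 1, *survival* rows the patches it occupied
in year 1, the response in both cases being presence in year 2.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PATCH_TYPES = ("papyrus", "shoreline", "broad_wetland")
VEG_COLUMNS = ("veg_disturbed", "veg_moderate", "veg_undisturbed", "veg_mixed")

#: covariates offered to the turnover models (moderate vegetation is the
#: reference category and never enters as a predictor).
MODEL_COVARIATES = (
    "area",
    "circularity",
    "veg_disturbed",
    "veg_undisturbed",
    "veg_mixed",
    "connectivity",
)

HA_TO_M2 = 10_000.0


class PatchValidationError(ValueError):
    """A patch table violates a structural invariant."""


@dataclass
class Patch:
    """One habitat fragment.

    Coordinates are projected (metres); ``area`` is in hectares.  The four
    vegetation proportions must sum to one.  ``parent_wetland_id`` links a
    papyrus patch to the broad wetland that encloses it.  ``density`` is an
    optional per-species relative density (birds/ha) keyed by species name.
    """

    patch_id: str
    patch_type: str
    x: float
    y: float
    area: float
    perimeter: float | None = None
    veg_disturbed: float = 0.0
    veg_moderate: float = 1.0
    veg_undisturbed: float = 0.0
    veg_mixed: float = 0.0
    parent_wetland_id: str | None = None
    density: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.patch_type not in PATCH_TYPES:
            raise PatchValidationError(
                f"patch {self.patch_id!r}: unknown patch_type {self.patch_type!r}"
            )
        if not self.area > 0:
            raise PatchValidationError(f"patch {self.patch_id!r}: area must be > 0")
        if self.perimeter is not None and not self.perimeter > 0:
            raise PatchValidationError(
                f"patch {self.patch_id!r}: perimeter must be > 0 when given"
            )
        props = [self.veg_disturbed, self.veg_moderate, self.veg_undisturbed, self.veg_mixed]
        if any(p < 0 or p > 1 for p in props):
            raise PatchValidationError(
                f"patch {self.patch_id!r}: vegetation proportions must lie in [0, 1]"
            )
        total = float(sum(props))
        if abs(total - 1.0) > 1e-3:
            raise PatchValidationError(
                f"patch {self.patch_id!r}: vegetation proportions sum to {total:.4f}, not 1"
            )
        if abs(total - 1.0) > 1e-6:
            # renormalize small rounding slack from hand-entered tables
            self.veg_disturbed /= total
            self.veg_moderate /= total
            self.veg_undisturbed /= total
            self.veg_mixed /= total

    @property
    def circularity(self) -> float | None:
        """Shape index 4*pi*area/perimeter**2 (1 for a circle), or None."""
        if self.perimeter is None:
            return None
        return compute_circularity(self.area * HA_TO_M2, self.perimeter)


class PatchNetwork:
    """An ordered, id-indexed collection of patches in one projected CRS."""

    def __init__(self, patches: Iterable[Patch], distance_unit: str = "m"):
        self.patches: dict[str, Patch] = {}
        for p in patches:
            if p.patch_id in self.patches:
                raise PatchValidationError(f"duplicate patch_id {p.patch_id!r}")
            self.patches[p.patch_id] = p
        if len(self.patches) < 2:
            raise PatchValidationError("a network needs at least 2 patches")
        self.distance_unit = distance_unit
        for p in self.patches.values():
            if p.parent_wetland_id is not None:
                parent = self.patches.get(p.parent_wetland_id)
                if parent is None:
                    raise PatchValidationError(
                        f"patch {p.patch_id!r}: parent_wetland_id "
                        f"{p.parent_wetland_id!r} names no patch"
                    )
                if parent.patch_type != "broad_wetland":
                    raise PatchValidationError(
                        f"patch {p.patch_id!r}: parent {parent.patch_id!r} is "
                        f"{parent.patch_type}, not broad_wetland"
                    )

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches.values())

    def __getitem__(self, patch_id: str) -> Patch:
        return self.patches[patch_id]

    @property
    def patch_ids(self) -> list[str]:
        return list(self.patches)

    def coordinates(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Flat patch table; density columns are ``density_<species>``."""
        rows = []
        for p in self:
            row = {
                "patch_id": p.patch_id,
                "patch_type": p.patch_type,
                "x": p.x,
                "y": p.y,
                "area": p.area,
                "perimeter": p.perimeter,
                "circularity": p.circularity,
                "veg_disturbed": p.veg_disturbed,
                "veg_moderate": p.veg_moderate,
                "veg_undisturbed": p.veg_undisturbed,
                "veg_mixed": p.veg_mixed,
                "parent_wetland_id": p.parent_wetland_id,
            }
            for sp, d in p.density.items():
                row[f"density_{sp}"] = d
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class OccupancyTable:
    """Presence/absence per (patch, species, year) over two consecutive years."""

    entries: dict[tuple[str, str, int], int]
    years: tuple[int, int]

    def __post_init__(self) -> None:
        y1, y2 = self.years
        if y2 != y1 + 1:
            raise PatchValidationError(f"years must be consecutive, got {self.years}")
        for key, v in self.entries.items():
            if v not in (0, 1):
                raise PatchValidationError(f"occupancy at {key} is {v!r}, not 0/1")
            if key[2] not in self.years:
                raise PatchValidationError(f"entry year {key[2]} outside {self.years}")

    @property
    def species(self) -> list[str]:
        return sorted({sp for (_, sp, _) in self.entries})

    def get(self, patch_id: str, species: str, year: int) -> int | None:
        return self.entries.get((patch_id, species, year))

    def surveyed_both_years(self, species: str) -> list[str]:
        """Patch ids with a record for this species in both years."""
        y1, y2 = self.years
        ids = []
        for (pid, sp, yr) in self.entries:
            if sp == species and yr == y1 and (pid, sp, y2) in self.entries:
                ids.append(pid)
        return sorted(set(ids))

    def occupancy_vector(self, patch_ids: Sequence[str], species: str, year: int) -> np.ndarray:
        """0/1 vector over patch_ids; unsurveyed patches count as absent sources."""
        return np.array(
            [self.entries.get((pid, species, year), 0) for pid in patch_ids], dtype=float
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"patch_id": pid, "species": sp, "year": yr, "present": v}
            for (pid, sp, yr), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class DistanceMatrix:
    """Symmetric nearest-edge (or point-to-point) distances between patches.

    The unit is recorded explicitly and never rescaled silently: the
    dispersal-kernel decay rate is per unit of this distance.
    """

    ids: list[str]
    d: np.ndarray
    unit: str = "m"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be 0")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")
        self._index = {pid: i for i, pid in enumerate(self.ids)}

    def submatrix(self, row_ids: Sequence[str], col_ids: Sequence[str]) -> np.ndarray:
        ri = [self._index[i] for i in row_ids]
        ci = [self._index[i] for i in col_ids]
        return self.d[np.ix_(ri, ci)]


@dataclass
class TurnoverDataset:
    """Model-ready rows for one turnover process of one species.

    ``kind`` is "colonization" (patches absent in year 1; y=1 means
    colonized) or "survival" (patches present in year 1; y=1 means the
    population survived).  ``data`` holds the response column ``y`` plus the
    covariates, indexed by patch_id.
    """

    kind: str
    species: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in ("colonization", "survival"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        if "y" not in self.data.columns:
            raise ValueError("dataset must contain a response column 'y'")
        if not self.data["y"].isin([0, 1]).all():
            raise ValueError("responses must be 0/1")
        covs = self.data.drop(columns="y")
        if not np.isfinite(covs.to_numpy(dtype=float)).all():
            raise ValueError("covariates must be finite")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["y"].sum())


@dataclass
class TurnoverCounts:
    """The four year-1 -> year-2 transition counts for one species."""

    colonized: int
    survived: int
    extinct: int
    vacant: int

    @property
    def surveyed(self) -> int:
        return self.colonized + self.survived + self.extinct + self.vacant


def compute_circularity(area: float, perimeter: float) -> float:
    """Shape circularity 4*pi*area/perimeter**2.

    ``area`` in m^2 and ``perimeter`` in m (any length unit works as long as
    area is in its square).  Equals 1 for a circle and falls toward 0 as the
    edge:area ratio grows; scale-invariant.
    """
    if not area > 0 or not perimeter > 0:
        raise ValueError("area and perimeter must be positive")
    return 4.0 * math.pi * area / perimeter**2


def pairwise_edge_distances(
    geometries_or_points, ids: Sequence[str] | None = None, unit: str = "m"
) -> DistanceMatrix:
    """Symmetric matrix of nearest edge-to-edge distances.

    Accepts shapely geometries (minimum boundary-to-boundary distance;
    overlapping or touching polygons give 0) or an (n, 2) array of projected
    point coordinates (Euclidean distance).  All features must share one
    projected CRS.
    """
    from shapely.geometry.base import BaseGeometry

    feats = list(geometries_or_points)
    if len(feats) < 2:
        raise ValueError("need at least 2 features")
    if ids is None:
        ids = [str(i) for i in range(len(feats))]
    ids = list(ids)
    if len(ids) != len(feats):
        raise ValueError("ids length mismatch")

    if isinstance(feats[0], BaseGeometry):
        n = len(feats)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = feats[i].distance(feats[j])
    else:
        pts = np.asarray(feats, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("point input must be an (n, 2) array")
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
    return DistanceMatrix(ids=ids, d=d, unit=unit)


# ---------------------------------------------------------------------------
# readers / writers

_REQUIRED_PATCH_COLUMNS = ("patch_id", "patch_type", "x", "y", "area") + VEG_COLUMNS


def _patches_from_frame(df: pd.DataFrame) -> list[Patch]:
    missing = [c for c in _REQUIRED_PATCH_COLUMNS if c not in df.columns]
    if missing:
        raise PatchValidationError(f"patch table missing required columns: {missing}")
    density_cols = [c for c in df.columns if c.startswith("density_")]
    patches = []
    for _, row in df.iterrows():
        density = {
            c[len("density_"):]: float(row[c]) for c in density_cols if pd.notna(row[c])
        }
        perim = row.get("perimeter")
        parent = row.get("parent_wetland_id")
        patches.append(
            Patch(
                patch_id=str(row["patch_id"]),
                patch_type=str(row["patch_type"]),
                x=float(row["x"]),
                y=float(row["y"]),
                area=float(row["area"]),
                perimeter=None if perim is None or pd.isna(perim) else float(perim),
                veg_disturbed=float(row["veg_disturbed"]),
                veg_moderate=float(row["veg_moderate"]),
                veg_undisturbed=float(row["veg_undisturbed"]),
                veg_mixed=float(row["veg_mixed"]),
                parent_wetland_id=None
                if parent is None or pd.isna(parent) or parent == ""
                else str(parent),
                density=density,
            )
        )
    return patches


def load_patch_table(
    patch_path, occupancy_path=None, format: str = "csv"
) -> tuple[PatchNetwork, OccupancyTable | None]:
    """Read a patch table (CSV or GeoJSON) and an optional occupancy CSV.

    The CSV dialect is the one the writers emit: one row per patch with the
    documented header; the occupancy file is long-format
    (patch_id, species, year, present).  Coordinates must be projected
    (metres); lat/long-looking input is refused rather than silently
    producing degenerate distances.
    """
    if format == "csv":
        df = pd.read_csv(patch_path)
    elif format == "geojson":
        with open(patch_path) as fh:
            gj = json.load(fh)
        from shapely.geometry import shape

        rows = []
        for feat in gj["features"]:
            props = dict(feat["properties"])
            geom = shape(feat["geometry"])
            props.setdefault("x", geom.centroid.x)
            props.setdefault("y", geom.centroid.y)
            props.setdefault("area", geom.area / HA_TO_M2)
            props.setdefault("perimeter", geom.length)
            rows.append(props)
        df = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown format {format!r}")

    if df["patch_id"].duplicated().any():
        dups = df.loc[df["patch_id"].duplicated(), "patch_id"].tolist()
        raise PatchValidationError(f"duplicate patch_id values: {dups}")
    # projected-CRS guard: coordinates that all fit in lat/long ranges are
    # almost certainly unprojected
    if df["x"].abs().max() <= 180 and df["y"].abs().max() <= 90:
        raise PatchValidationError(
            "coordinates look like lat/long; supply projected coordinates in metres"
        )
    network = PatchNetwork(_patches_from_frame(df))

    occupancy = None
    if occupancy_path is not None:
        occupancy = load_occupancy_table(occupancy_path)
    return network, occupancy


def load_occupancy_table(path) -> OccupancyTable:
    df = pd.read_csv(path)
    required = ("patch_id", "species", "year", "present")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PatchValidationError(f"occupancy table missing columns: {missing}")
    bad = df.loc[~df["present"].isin([0, 1])]
    if len(bad):
        raise PatchValidationError(
            f"occupancy values outside {{0,1}} for patch_ids {bad['patch_id'].tolist()[:5]}"
        )
    years = tuple(sorted(df["year"].unique()))
    if len(years) != 2:
        raise PatchValidationError(f"expected exactly two survey years, got {years}")
    entries = {
        (str(r.patch_id), str(r.species), int(r.year)): int(r.present)
        for r in df.itertuples()
    }
    return OccupancyTable(entries=entries, years=(int(years[0]), int(years[1])))


def write_patch_table(network: PatchNetwork, path) -> None:
    network.to_frame().to_csv(path, index=False)


def write_occupancy_table(occupancy: OccupancyTable, path) -> None:
    occupancy.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# turnover datasets


def suitable_patch_ids(network: PatchNetwork, species_params) -> list[str]:
    """Patches of types the species uses (papyrus always; shoreline and
    broad wetland only when the species' habitat-use flags say so)."""
    keep = []
    for p in network:
        if p.patch_type == "shoreline" and not species_params.uses_shoreline:
            continue
        if p.patch_type == "broad_wetland" and not species_params.uses_broad:
            continue
        keep.append(p.patch_id)
    return keep


def covariate_frame(
    network: PatchNetwork,
    patch_ids: Sequence[str],
    connectivity: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Model covariates for the given patches (year-2 habitat data).

    Patches without a perimeter have no circularity; they are dropped with a
    warning rather than imputed.  ``connectivity`` maps patch_id -> S_i.
    """
    rows, kept = [], []
    for pid in patch_ids:
        p = network[pid]
        circ = p.circularity
        if circ is None:
            logger.warning("patch %s: no perimeter, dropped (circularity missing)", pid)
            continue
        row = {
            "area": p.area,
            "circularity": circ,
            "veg_disturbed": p.veg_disturbed,
            "veg_undisturbed": p.veg_undisturbed,
            "veg_mixed": p.veg_mixed,
        }
        if connectivity is not None:
            row["connectivity"] = float(connectivity[pid])
        rows.append(row)
        kept.append(pid)
    return pd.DataFrame(rows, index=pd.Index(kept, name="patch_id"))


def build_turnover_datasets(
    occupancy: OccupancyTable,
    species: str,
    covariates: pd.DataFrame,
) -> tuple[TurnoverDataset, TurnoverDataset, TurnoverCounts]:
    """Partition surveyed suitable patches into the two turnover datasets.

    ``covariates`` is indexed by patch_id and already restricted to patches
    suitable for the species (see :func:`suitable_patch_ids`); it carries
    the year-2 habitat covariates plus the year-1-based connectivity score.
    Patches unsurveyed in either year are excluded and logged.

    Returns the colonization dataset, the survival dataset, and the four
    transition counts (colonized, survived, extinct, vacant).
    """
    if species not in occupancy.species:
        raise KeyError(f"species {species!r} not in occupancy table")
    y1, y2 = occupancy.years
    surveyed = [pid for pid in occupancy.surveyed_both_years(species) if pid in covariates.index]
    dropped = set(covariates.index) - set(surveyed)
    if dropped:
        logger.info(
            "%s: %d suitable patches unsurveyed in one or both years, excluded",
            species,
            len(dropped),
        )

    col_rows, surv_rows = [], []
    counts = {"colonized": 0, "survived": 0, "extinct": 0, "vacant": 0}
    for pid in surveyed:
        p1 = occupancy.get(pid, species, y1)
        p2 = occupancy.get(pid, species, y2)
        row = covariates.loc[pid].to_dict()
        if p1 == 0:
            row["y"] = p2
            col_rows.append((pid, row))
            counts["colonized" if p2 else "vacant"] += 1
        else:
            row["y"] = p2
            surv_rows.append((pid, row))
            counts["survived" if p2 else "extinct"] += 1

    def _frame(rows):
        if not rows:
            return pd.DataFrame(columns=list(covariates.columns) + ["y"])
        idx = pd.Index([pid for pid, _ in rows], name="patch_id")
        return pd.DataFrame([r for _, r in rows], index=idx)

    colonization = TurnoverDataset(kind="colonization", species=species, data=_frame(col_rows))
    survival = TurnoverDataset(kind="survival", species=species, data=_frame(surv_rows))
    return colonization, survival, TurnoverCounts(**counts)
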