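"""Multi-species overlap maps over a harmonized patch network.

Per-species quadrant classifications are first harmonized onto one
comparable patch universe: broad-wetland predictions for the species that
occupy broad wetland are allocated down to the papyrus patches each
wetland contains (the wetland's own unit dissolves once it has contained
patches), and shoreline fringing patches are forced to "marginal" for the
species that never use them.  Overlap counts per patch then tally, for
each category and for the six derived map layers, how many of the K
species fall in it:

    (a) high resistance & high resilience
    (b) low resistance & low resilience
    (c) high resistance (any resilience)
    (d) high resistance & low resilience
    (e) high resilience (any resistance)
    (f) low resistance & high resilience
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .patch_io import PatchNetwork
from .persistence import Category, PersistenceResult

logger = logging.getLogger(__name__)

PANELS = ("a", "b", "c", "d", "e", "f")

#: which categories each map layer counts
PANEL_CATEGORIES = {
    "a": {Category.RESISTANT_AND_RESILIENT},
    "b": {Category.MARGINAL},
    "c": {Category.RESISTANT_AND_RESILIENT, Category.RESISTANT_ONLY},
    "d": {Category.RESISTANT_ONLY},
    "e": {Category.RESISTANT_AND_RESILIENT, Category.RESILIENT_ONLY},
    "f": {Category.RESILIENT_ONLY},
}


def harmonized_patch_ids(network: PatchNetwork) -> list[str]:
    """The comparable patch universe: papyrus and shoreline patches, plus
    any broad wetland that contains no papyrus patch (kept with a warning)."""
    contained_parents = {
        p.parent_wetland_id for p in network if p.parent_wetland_id is not None
    }
    ids = []
    for p in network:
        if p.patch_type in ("papyrus", "shoreline"):
            ids.append(p.patch_id)
        elif p.patch_type == "broad_wetland":
            if p.patch_id not in contained_parents:
                logger.warning(
                    "broad wetland %s contains no papyrus patch; kept as its own unit",
                    p.patch_id,
                )
                ids.append(p.patch_id)
    return ids


def allocate_broad_to_papyrus(
    predictions: dict[str, PersistenceResult], network: PatchNetwork
) -> dict[str, PersistenceResult]:
    """Give every contained papyrus patch its parent broad wetland's
    prediction (probabilities and category), for a broad-wetland species.

    Patches without a parent are unchanged.  A parent id that names a
    non-broad-wetland patch is a network-validation error and cannot occur
    in a validated :class:`PatchNetwork`; a parent with no prediction
    raises.
    """
    out = dict(predictions)
    for p in network:
        if p.parent_wetland_id is None:
            continue
        parent = network[p.parent_wetland_id]
        if parent.patch_type != "broad_wetland":
            raise ValueError(
                f"patch {p.patch_id!r}: parent {parent.patch_id!r} is not a broad wetland"
            )
        if parent.patch_id not in predictions:
            if p.patch_id in predictions:
                # already-allocated map (the wetland unit was dissolved):
                # the child keeps its inherited prediction
                continue
            raise KeyError(
                f"no prediction for broad wetland {parent.patch_id!r} "
                f"(needed by contained patch {p.patch_id!r})"
            )
        src = predictions[parent.patch_id]
        out[p.patch_id] = PersistenceResult(
            patch_id=p.patch_id,
            species=src.species,
            S_prob=src.S_prob,
            C_prob=src.C_prob,
            P_no_rescue=src.P_no_rescue,
            P_rescue=src.P_rescue,
            category=src.category,
        )
    return out


def mark_marginal_for_nonusers(
    predictions: dict[str, PersistenceResult],
    network: PatchNetwork,
    uses_shoreline: bool,
) -> dict[str, PersistenceResult]:
    """Force shoreline patches to "marginal" for a species that does not use
    them (overlap layer only; per-species maps keep the model output)."""
    if uses_shoreline:
        return dict(predictions)
    out = dict(predictions)
    for p in network:
        if p.patch_type == "shoreline" and p.patch_id in out:
            r = out[p.patch_id]
            out[p.patch_id] = PersistenceResult(
                patch_id=r.patch_id,
                species=r.species,
                S_prob=r.S_prob,
                C_prob=r.C_prob,
                P_no_rescue=r.P_no_rescue,
                P_rescue=r.P_rescue,
                category=Category.MARGINAL,
            )
    return out


def harmonize(
    predictions: dict[str, PersistenceResult],
    network: PatchNetwork,
    uses_shoreline: bool,
    uses_broad: bool,
) -> dict[str, PersistenceResult]:
    """Apply broad-wetland allocation and shoreline marking, then restrict
    to the harmonized patch universe.  Idempotent.

    For a species that does not use shoreline patches, shoreline entries
    missing from its predictions are synthesized as marginal so every
    species covers the same universe.
    """
    preds = dict(predictions)
    if uses_broad:
        preds = allocate_broad_to_papyrus(preds, network)
    species = next(iter(preds.values())).species if preds else ""
    universe = harmonized_patch_ids(network)
    # patch types outside the species' habitat carry no model prediction;
    # on the shared layer they are unusable, i.e. marginal
    for pid in universe:
        ptype = network[pid].patch_type
        unusable = (ptype == "shoreline" and not uses_shoreline) or (
            ptype == "broad_wetland" and not uses_broad
        )
        if pid not in preds and unusable:
            preds[pid] = PersistenceResult(
                patch_id=pid,
                species=species,
                S_prob=float("nan"),
                C_prob=float("nan"),
                P_no_rescue=float("nan"),
                P_rescue=float("nan"),
                category=Category.MARGINAL,
            )
    preds = mark_marginal_for_nonusers(preds, network, uses_shoreline)
    return {pid: preds[pid] for pid in universe if pid in preds}


@dataclass
class OverlapMap:
    """Per patch: species counts per category and per map layer."""

    counts: pd.DataFrame  # index patch_id, columns = category values
    panels: pd.DataFrame  # index patch_id, columns = PANELS
    species_total: int

    def to_long(self) -> pd.DataFrame:
        long = self.panels.reset_index().melt(
            id_vars="patch_id", var_name="panel", value_name="count"
        )
        return long.sort_values(["panel", "patch_id"]).reset_index(drop=True)


def overlap_counts(per_species: dict[str, dict[str, PersistenceResult]]) -> OverlapMap:
    """Combine harmonized per-species classification maps into overlap
    counts.  All maps must cover exactly the same patch set."""
    if not per_species:
        raise ValueError("no species maps supplied")
    ids_sets = {sp: set(m.keys()) for sp, m in per_species.items()}
    universe = ids_sets[next(iter(ids_sets))]
    for sp, ids in ids_sets.items():
        if ids != universe:
            diff = ids.symmetric_difference(universe)
            raise ValueError(
                f"species {sp!r} map not harmonized: mismatched patches {sorted(diff)[:5]}"
            )
    index = sorted(universe)
    cat_cols = [c.value for c in Category]
    counts = pd.DataFrame(0, index=pd.Index(index, name="patch_id"), columns=cat_cols)
    for sp, m in per_species.items():
        for pid, r in m.items():
            counts.loc[pid, r.category.value] += 1
    panels = pd.DataFrame(0, index=counts.index, columns=list(PANELS))
    for panel, cats in PANEL_CATEGORIES.items():
        panels[panel] = sum(counts[c.value] for c in cats)
    return OverlapMap(counts=counts, panels=panels, species_total=len(per_species))
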