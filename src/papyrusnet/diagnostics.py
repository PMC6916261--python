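"""Residual spatial-structure diagnostics and turnover summary tables.

The empirical semivariogram gamma(h) = (1/2N_h) * sum (z_i - z_j)^2 over
point pairs whose separation falls in lag bin h is used to check model
residuals for remaining spatial structure: a flat variogram near the
residual variance (the white-noise sill) indicates none.  Residuals are
response residuals (observed 0/1 minus predicted probability) by default;
deviance residuals are available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .patch_io import TurnoverCounts


@dataclass
class Semivariogram:
    bin_centers: np.ndarray
    gamma: np.ndarray  # NaN where a bin holds no pair
    pair_counts: np.ndarray
    bin_edges: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "gamma": self.gamma,
                "pairs": self.pair_counts,
            }
        )


def default_bins(coordinates: np.ndarray, n_bins: int = 10, quantile: float = 0.6) -> np.ndarray:
    """Equal-width lag bins from 0 to the given quantile of pairwise
    distances (standard geostatistical cutoff)."""
    pts = np.asarray(coordinates, dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    dmax = np.quantile(d[np.triu_indices(len(pts), k=1)], quantile)
    return np.linspace(0.0, float(dmax), n_bins + 1)


def empirical_semivariogram(
    residuals: np.ndarray,
    coordinates: np.ndarray,
    bin_edges: np.ndarray | None = None,
) -> Semivariogram:
    """Matheron's classical estimator on irregular points.

    Bins with no pairs get gamma = NaN (undefined, not zero).
    """
    z = np.asarray(residuals, dtype=float)
    pts = np.asarray(coordinates, dtype=float)
    if len(z) != len(pts) or len(z) < 2:
        raise ValueError("need >= 2 points with matching residuals")
    if bin_edges is None:
        bin_edges = default_bins(pts)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")

    iu, ju = np.triu_indices(len(z), k=1)
    d = np.sqrt(((pts[iu] - pts[ju]) ** 2).sum(axis=1))
    sq = (z[iu] - z[ju]) ** 2
    which = np.digitize(d, bin_edges) - 1
    nb = len(bin_edges) - 1
    gamma = np.full(nb, np.nan)
    counts = np.zeros(nb, dtype=int)
    for b in range(nb):
        mask = which == b
        counts[b] = int(mask.sum())
        if counts[b]:
            gamma[b] = 0.5 * sq[mask].mean()
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return Semivariogram(
        bin_centers=centers, gamma=gamma, pair_counts=counts, bin_edges=bin_edges
    )


def response_residuals(observed: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    return np.asarray(observed, dtype=float) - np.asarray(predicted, dtype=float)


def deviance_residuals(observed: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    y = np.asarray(observed, dtype=float)
    p = np.clip(np.asarray(predicted, dtype=float), 1e-12, 1 - 1e-12)
    dev = -2 * (y * np.log(p) + (1 - y) * np.log1p(-p))
    return np.sign(y - p) * np.sqrt(dev)


def turnover_summary(per_species: dict[str, TurnoverCounts]) -> pd.DataFrame:
    """One row per species: surveyed, colonized, survived, extinct, vacant.

    Raises if the four transition counts do not add up to the surveyed
    total (they always should, by construction).
    """
    rows = []
    for sp, c in per_species.items():
        total = c.colonized + c.survived + c.extinct + c.vacant
        if total != c.surveyed:
            raise AssertionError(f"{sp}: counts {total} != surveyed {c.surveyed}")
        rows.append(
            {
                "species": sp,
                "surveyed": c.surveyed,
                "colonized": c.colonized,
                "survived": c.survived,
                "extinct": c.extinct,
                "vacant": c.vacant,
            }
        )
    return pd.DataFrame(rows)
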