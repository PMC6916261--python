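"""Estimate the dispersal-kernel decay rate from colonization events.

Runs the profile-likelihood estimator on a simulation with known truth
(400 patches in a 500 m extent, true decay 0.1/m, colonization driven by
incidence-function connectivity) and on a response-shuffled control where
the flat-likelihood diagnostic must fire.  Writes the profile curves.

Outputs: results/alpha_profile.csv, results/alpha_estimate.json
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from papyrusnet import (
    SpeciesTruth,
    SyntheticConfig,
    build_turnover_datasets,
    covariate_frame,
    estimate_alpha,
    generate_network,
    simulate_occupancy,
    suitable_patch_ids,
    two_year_table,
)
from papyrusnet.connectivity import connectivity_vector, network_capacities

OUT = Path(__file__).resolve().parent.parent / "results"
TRUE_ALPHA = 0.1
GRID = np.geomspace(1e-3, 1.0, 200)


def main() -> None:
    truth = SpeciesTruth(
        species="sp",
        alpha=TRUE_ALPHA,
        beta_colonization={"intercept": -2.5, "connectivity": 1.0},
        beta_survival={"intercept": 1.0},
    )
    cfg = SyntheticConfig(n_patches=400, extent=500.0, species=[truth], seed=0)
    network, distances = generate_network(cfg)
    history, _ = simulate_occupancy(network, distances, cfg)
    occ = two_year_table(history, cfg.first_year)

    params = truth.params()
    ids = suitable_patch_ids(network, params)
    caps = network_capacities(network, "sp")
    occ1 = {pid: occ.get(pid, "sp", cfg.first_year) or 0 for pid in network.patch_ids}
    S = connectivity_vector(ids, occ1, caps, params, distances)
    cov = covariate_frame(network, ids, connectivity=dict(zip(ids, S)))
    colonization, _, _ = build_turnover_datasets(occ, "sp", cov)

    fit = estimate_alpha(colonization, caps, occ1, distances, alpha_grid=GRID)
    print(
        f"true alpha {TRUE_ALPHA}/m -> estimate {fit.alpha:.4f}/m "
        f"(mean dispersal {1 / fit.alpha:.1f} m); flat={fit.flat}, "
        f"boundary={fit.at_boundary}"
    )

    rng = np.random.default_rng(0)
    shuffled = colonization
    shuffled.data["y"] = rng.permutation(shuffled.data["y"].to_numpy())
    null_fit = estimate_alpha(shuffled, caps, occ1, distances, alpha_grid=GRID)
    print(f"shuffled-response control: flat diagnostic fired = {null_fit.flat}")

    OUT.mkdir(exist_ok=True)
    pd.DataFrame(
        {"alpha": fit.grid, "loglik": fit.loglik, "loglik_shuffled": null_fit.loglik}
    ).to_csv(OUT / "alpha_profile.csv", index=False)
    with open(OUT / "alpha_estimate.json", "w") as fh:
        json.dump(
            {
                "true_alpha": TRUE_ALPHA,
                "estimate": fit.alpha,
                "flat": fit.flat,
                "at_boundary": fit.at_boundary,
                "control_flat": null_fit.flat,
            },
            fh,
            indent=2,
        )


if __name__ == "__main__":
    main()
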