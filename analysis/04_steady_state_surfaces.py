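"""Map the steady-state persistence surfaces and check them by simulation.

Evaluates the no-rescue and rescue closed forms over the (S, C) unit
square, verifies both against long Markov-chain simulations at a few
parameter pairs, and plots the two surfaces with the S + C = 1 balance
line (P = 0.5 exactly on that line without rescue; above 0.5 below the
line once same-year rescue operates).

Outputs: results/steady_state_grid.csv, results/steady_state_check.csv,
         results/steady_state_surfaces.png
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from papyrusnet import (
    markov_equilibrium_simulation,
    steady_state_no_rescue,
    steady_state_rescue,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    grid = np.linspace(0.0, 0.99, 100)
    rows = [
        {
            "S": s,
            "C": c,
            "P_no_rescue": steady_state_no_rescue(s, c),
            "P_rescue": steady_state_rescue(s, c),
        }
        for s in grid
        for c in grid
    ]
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "steady_state_grid.csv", index=False)

    checks = []
    for s, c in ((0.8, 0.3), (0.5, 0.4), (0.3, 0.7)):
        for rescue in (False, True):
            closed = steady_state_rescue(s, c) if rescue else steady_state_no_rescue(s, c)
            sim = markov_equilibrium_simulation(
                s, c, rescue=rescue, steps=100_000, burn_in=1_000, seed=1
            )
            checks.append(
                {"S": s, "C": c, "rescue": rescue, "closed_form": closed,
                 "simulated": sim, "abs_err": abs(sim - closed)}
            )
            print(
                f"S={s} C={c} rescue={rescue}: closed {closed:.4f}, "
                f"simulated {sim:.4f}"
            )
    checks = pd.DataFrame(checks)
    checks.to_csv(OUT / "steady_state_check.csv", index=False)
    assert (checks["abs_err"] < 0.01).all(), "simulation strayed from closed form"

    fig, axes = plt.subplots(1, 2, figsize=(10, 4.2), sharey=True)
    for ax, col, title in (
        (axes[0], "P_no_rescue", "no rescue: P = C/(1-S+C)"),
        (axes[1], "P_rescue", "rescue: P = C/(1-S+SC)"),
    ):
        P = df.pivot(index="C", columns="S", values=col).to_numpy()
        im = ax.imshow(
            P, origin="lower", extent=[0, 0.99, 0, 0.99], vmin=0, vmax=1,
            cmap="viridis", aspect="auto",
        )
        ax.plot([0, 0.99], [0.99, 0], "w--", lw=1, label="S + C = 1")
        ax.set_xlabel("annual survival S (resistance)")
        ax.set_title(title)
        ax.legend(loc="lower left", fontsize=8)
    axes[0].set_ylabel("annual colonization C (resilience)")
    fig.colorbar(im, ax=axes, label="steady-state persistence P")
    fig.savefig(OUT / "steady_state_surfaces.png", dpi=150)
    print(f"wrote {OUT / 'steady_state_surfaces.png'}")


if __name__ == "__main__":
    main()
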