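import numpy as np
import pytest

from papyrusnet import (
    OccupancyTable,
    Patch,
    PatchNetwork,
    SyntheticConfig,
    generate_network,
    pairwise_edge_distances,
    simulate_occupancy,
    two_year_table,
)


def make_patch(pid="p0", **kw):
    defaults = dict(
        patch_id=pid,
        patch_type="papyrus",
        x=500_000.0,
        y=9_800_000.0,
        area=1.0,
        perimeter=400.0,
        veg_disturbed=0.1,
        veg_moderate=0.5,
        veg_undisturbed=0.3,
        veg_mixed=0.1,
    )
    defaults.update(kw)
    return Patch(**defaults)


@pytest.fixture
def toy_network():
    """Four papyrus patches on a 1 km line, realizing each transition type."""
    patches = [
        make_patch("a", x=500_000.0),
        make_patch("b", x=500_100.0, area=2.0, perimeter=600.0),
        make_patch("c", x=500_500.0, area=0.5, perimeter=300.0),
        make_patch("d", x=501_000.0),
    ]
    return PatchNetwork(patches)


@pytest.fixture
def toy_occupancy():
    """a: colonized, b: survived, c: extinct, d: stayed vacant."""
    entries = {}
    for pid, (y1, y2) in {"a": (0, 1), "b": (1, 1), "c": (1, 0), "d": (0, 0)}.items():
        entries[(pid, "sp", 2014)] = y1
        entries[(pid, "sp", 2015)] = y2
    return OccupancyTable(entries=entries, years=(2014, 2015))


@pytest.fixture
def toy_distances(toy_network):
    return pairwise_edge_distances(toy_network.coordinates(), ids=toy_network.patch_ids)


@pytest.fixture(scope="session")
def sim_default():
    """One simulated two-year study at the default study conditions."""
    cfg = SyntheticConfig(n_patches=300, seed=11)
    network, distances = generate_network(cfg)
    history, log = simulate_occupancy(network, distances, cfg)
    occupancy = two_year_table(history, cfg.first_year)
    return cfg, network, distances, history, log, occupancy
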