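import numpy as np
import pytest

from colonyfate import colony_quant as cq
from colonyfate import rd_model as rd
from colonyfate import synthetic_colonies as sc


@pytest.fixture(scope="session")
def radial_domain():
    return rd.build_domain("radial-1D", 250.0, 500.0, 2.5)


@pytest.fixture(scope="session")
def sb_fields_24h(radial_domain):
    """Default SB run, 24 h, reused by several tests."""
    return rd.simulate(rd.default_params("sb"), radial_domain,
                       T=24.0, save_every=4.0, seed=1)


@pytest.fixture(scope="session")
def ring_plate():
    """Noise-free peripheral-ring plate plus its quantified ColonySet."""
    spec = sc.PlateSpec(
        n_wells=1, colonies_per_well=6, off_colony_rate=1.0,
        channel_models={"ch_A": sc.ChannelModel(profile="peripheral-ring",
                                                gain=100.0)},
        seed=7)
    cells, truth = sc.generate_plate(spec)
    cs = cq.filter_colonies(cq.assign_colonies(cells), nominal_diameter=500.0)
    return cells, truth, cs


def two_colony_cells(int_a=10.0, int_b=30.0, n=300, seed=0):
    """Two well-separated uniform-intensity colonies (test helper)."""
    rng = np.random.default_rng(seed)
    rows = []
    for cx, val in ((500.0, int_a), (3000.0, int_b)):
        u, th = rng.random(n), rng.random(n) * 2 * np.pi
        r = 250.0 * np.sqrt(u)
        for i in range(n):
            rows.append(["W00", cx + r[i] * np.cos(th[i]),
                         500.0 + r[i] * np.sin(th[i]), val])
    import pandas as pd
    return pd.DataFrame(rows, columns=["well", "x", "y", "ch"])
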