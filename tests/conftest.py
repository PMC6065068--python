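import numpy as np
import pytest

from invintro import coalescent as co
from invintro import invasion as inv


@pytest.fixture(scope="session")
def iberia_grid():
    return inv.build_grid(inv.iberia_config())


@pytest.fixture(scope="session")
def iberia_samples(iberia_grid):
    return co.default_samples(iberia_grid)


def make_chain_config(n: int, donor_demes=(), t_gen: int = 200,
                      source_col: int = 0) -> inv.ScenarioConfig:
    """1 x n chain world (row 0), donor occupying the given columns."""
    land = np.ones((1, n), dtype=bool)
    donor = np.zeros((1, n), dtype=bool)
    for c in donor_demes:
        donor[0, c] = True
    return inv.ScenarioConfig(n_cols=n, n_rows=1, land_mask=land,
                              donor_mask=donor, source_deme=(0, source_col),
                              t_start_gen=t_gen)


@pytest.fixture(scope="session")
def small_history():
    """Small 6x4 world with a short history: fast enough for kernel-level
    property tests while exercising co-occupancy and colonization."""
    land = np.ones((4, 6), dtype=bool)
    donor = np.zeros((4, 6), dtype=bool)
    donor[2:, :] = True
    cfg = inv.ScenarioConfig(n_cols=6, n_rows=4, land_mask=land,
                             donor_mask=donor, source_deme=(0, 0),
                             t_start_gen=400)
    grid = inv.build_grid(cfg)
    params = inv.SimParams(K_G=200, K_T=100, G=0.5, M=0.1,
                           A_fd=0.01, A_df=0.01)
    history = inv.run_forward(grid, params, seed=5)
    assert history.replaced
    return history


@pytest.fixture(scope="session")
def small_samples(small_history):
    grid = small_history.grid
    demes = np.array([grid.deme_at(0, 1), grid.deme_at(1, 2), grid.deme_at(1, 4),
                      grid.deme_at(2, 2), grid.deme_at(3, 5)])
    rc = grid.coords[demes].astype(float)
    dist = np.sqrt(((rc - rc[0]) ** 2).sum(axis=1)) * 50.0
    return co.SampleMap(populations=["S1", "S2", "S3", "N1", "N2"],
                        demes=demes, distance_km=dist, n_lineages=2)
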