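"""Shared fixtures: small simulated panels and phenotypes.

All fixtures are generated programmatically with fixed seeds; session
scope keeps the pedigree simulations to one run each.
"""

import numpy as np
import pandas as pd
import pytest

from mpqtl import (
    GenomeGrid,
    PlantedQtl,
    SimConfig,
    plant_genetic_values,
    simulate_panel,
    simulate_vials,
)


@pytest.fixture(scope="session")
def toy_grid():
    return GenomeGrid.toy(arm_kb=3000, arms=("2L", "2R"))


@pytest.fixture(scope="session")
def null_panel(toy_grid):
    """150-RIL panel with no planted QTL."""
    cfg = SimConfig(n_ril=150, grid=toy_grid, seed=101)
    mosaics, panel = simulate_panel(cfg)
    return cfg, mosaics, panel


@pytest.fixture(scope="session")
def qtl_panel(toy_grid):
    """300-RIL panel with a major planted QTL (founders 1-3 resistant)."""
    qtl = PlantedQtl("q1", "2L", 1500, frozenset({1, 2, 3}), 5.2)
    cfg = SimConfig(n_ril=300, grid=toy_grid, qtl_list=[qtl], n_vials_per_ril=2,
                    sigma2_ril=1.0, sigma2_date=0.5, sigma2_resid=0.9, seed=202)
    mosaics, panel = simulate_panel(cfg)
    genetic = plant_genetic_values(mosaics, cfg.qtl_list, cfg.grid)
    vials = simulate_vials(genetic, cfg)
    return cfg, panel, vials


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
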