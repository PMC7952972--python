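"""Shared fixtures: genomes, grids and simulated reference panels."""

import dataclasses

import numpy as np
import pytest

import pgtcnv as P


@pytest.fixture(scope="session")
def full_map():
    return P.load_cytoband_map()


@pytest.fixture(scope="session")
def reduced_map():
    return P.reduced_cytoband_map()


@pytest.fixture(scope="session")
def full_grid(full_map):
    return P.build_bin_grid(full_map, seed=0)


@pytest.fixture(scope="session")
def reduced_grid(reduced_map):
    return P.build_bin_grid(reduced_map, seed=0)


@pytest.fixture(scope="session")
def sim_config():
    return P.SimulationConfig()


@pytest.fixture(scope="session")
def low_noise_config():
    """Minimal-dispersion regime for parameter-recovery checks."""
    return dataclasses.replace(P.SimulationConfig(), overdispersion=0.001,
                               dropout_prob=0.0, failure_prob=0.0)


def make_panel(grid, cfg, n=20, seed=777):
    rng = np.random.default_rng(seed)
    normals = [
        P.simulate_blastomere_counts([], "XX" if i % 2 else "XY", grid, cfg,
                                     rng, sample_id=f"normal{i}")
        for i in range(n)
    ]
    return P.build_reference(normals, grid)


@pytest.fixture(scope="session")
def reduced_panel(reduced_grid, sim_config):
    return make_panel(reduced_grid, sim_config)


@pytest.fixture(scope="session")
def full_panel(full_grid, sim_config):
    return make_panel(full_grid, sim_config)


@pytest.fixture(scope="session")
def full_panel_low(full_grid, low_noise_config):
    return make_panel(full_grid, low_noise_config)
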