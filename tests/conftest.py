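"""Shared fixtures: the default synthetic genome, contact matrix and PLA
image set, generated once per session (all generators are seeded and pure,
so sharing is safe)."""

from __future__ import annotations

import numpy as np
import pytest

import replimap as rm


@pytest.fixture(scope="session")
def default_genome():
    """Default 10-Mb genome at 50-kb windows, seed 1."""
    cfg = rm.SimGenomeConfig(seed=1)
    grid, table, truth = rm.simulate_genome(cfg)
    return cfg, grid, table, truth


@pytest.fixture(scope="session")
def default_contacts(default_genome):
    """200-bin contact matrix from the default genome's compartments."""
    _, _, _, truth = default_genome
    return rm.simulate_contact_matrix(truth.compartment,
                                      same_compartment_boost=1.0, seed=1)


@pytest.fixture(scope="session")
def default_pla():
    """Default PLA image set: 60 nuclei per arm, lambda 4 (early) vs 1 (late)."""
    cfg = rm.SimPlaConfig(seed=1)
    images, truth = rm.simulate_pla_images(cfg)
    return cfg, images, truth


@pytest.fixture(scope="session")
def rt_track(default_genome):
    _, _, table, _ = default_genome
    return table["rt"].to_numpy()


@pytest.fixture(scope="session")
def compartment_sign(default_genome):
    _, _, _, truth = default_genome
    return np.where(truth.compartment == "A", 1, -1)
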