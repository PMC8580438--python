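"""Shared fixtures: small synthetic worlds and reference assemblages."""

import numpy as np
import pytest

from provdiv import ingest, synth
from provdiv.synth import _hoppe_urn


def _gridded(world):
    kept = ingest.filter_records(world.records)
    cells = ingest.grid_records(kept)
    retained, _ = ingest.filter_cells(cells)
    matrix, env = ingest.build_matrix(retained, world.env)
    return matrix, env


@pytest.fixture(scope="session")
def small_config():
    """A 3-province world small enough for fast unit tests."""
    return synth.SynthConfig(
        n_cells=36,
        K=3,
        transition_width=2,
        pool_size=120,
        richness_range=(50, 25),
        effort_range=(150, 1200),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return synth.generate_world(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_world):
    matrix, env = _gridded(small_world)
    return matrix, env


@pytest.fixture(scope="session")
def default_world():
    """The full default world (120 cells, 5 provinces), shared read-only."""
    return synth.generate_world(synth.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_matrix(default_world):
    matrix, env = _gridded(default_world)
    return matrix, env


@pytest.fixture(scope="session")
def logseries_counts():
    """Abundance vector of one log-series assemblage (urn, n=2000)."""
    rng = np.random.default_rng(11)
    pop = _hoppe_urn(2000, 20.0, rng)
    counts = np.bincount(pop)
    return counts[counts > 0]
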