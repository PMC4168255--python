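"""Shared fixtures: a small synthetic world exercising every stage.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from consenm import (
    ScenarioDelta,
    build_grid,
    generate_climate,
    generate_species,
    sample_occurrences,
    standardize_climate,
)

GRID_EXTENT = (0.0, 0.0, 200.0, 200.0)
CELL = 10.0

DELTAS = [
    ScenarioDelta("gcm1", (3.0, 150.0, -80.0, 4.0)),
    ScenarioDelta("gcm2", (2.2, 100.0, -40.0, 2.0), ns_gradient=(1.0, 0.0, 120.0, 0.0)),
]


@pytest.fixture(scope="session")
def grid20():
    """20 x 20 fully masked grid of 10-unit cells."""
    return build_grid(GRID_EXTENT, CELL)


@pytest.fixture(scope="session")
def climate(grid20):
    """Current climate plus two pseudo-GCM futures."""
    return generate_climate(grid20, seed=11, deltas=DELTAS)


@pytest.fixture(scope="session")
def env(climate):
    return standardize_climate(climate)


@pytest.fixture(scope="session")
def truth(grid20, climate):
    """Eight species with known Gaussian niches."""
    return generate_species(8, grid20, climate, seed=23)


@pytest.fixture(scope="session")
def wide_species(grid20, climate):
    """A single broad-niche species abundantly and unbiasedly sampled:
    its occupied-cell set is the presence data for recovery tests."""
    t = generate_species(
        1, grid20, climate,
        niche_hyperparams={"breadth_factor_range": (0.8, 0.8),
                           "max_occupancy_range": (0.9, 0.9)},
        seed=5,
    )
    occ = sample_occurrences(t, climate, grid20, effort_per_species=600, seed=6)
    cells = np.unique(
        [cid for cid in (_cell_of(r, grid20) for r in occ.records) if cid >= 0]
    )
    return t, cells


def _cell_of(record, grid):
    from consenm import point_to_cell

    _, x, y, _ = record
    return point_to_cell(x, y, grid)
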