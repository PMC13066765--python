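import numpy as np
import pandas as pd
import pytest

from betascape.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast, fully-featured simulation config for smoke/e2e tests."""
    return SimulationConfig(
        n_landscapes=12,
        cell_size=400.0,
        habitat_amount_range=(0.05, 0.95),
        fragmentation_nuclei_range=(1, 12),
        inventories_per_landscape_range=(2, 5),
        pool_size=100,
        distance_decay_rate=0.5,
        homogenization_strength=2.0,
        endemism_cover_coupling=2.0,
        cover_homogenization=1.0,
        alpha_mean=35.0,
        individuals_per_inventory=200,
        seed=11,
    )


@pytest.fixture
def inventory_fixture():
    """Five inventories: one failing the effort rule."""
    return pd.DataFrame(
        {
            "inventory_id": [f"I{i}" for i in range(1, 6)],
            "x": [1.0, 2.0, 3.0, 4.0, 5.0],
            "y": [1.0, 1.5, 2.0, 2.5, 3.0],
            "year": [2001, 1994, 2010, 2005, 2000],
            "effort_ha": [0.5, 0.05, 0.25, 1.0, 0.1],
            "dbh_cutoff_cm": [5.0, 5.0, 10.0, 5.0, 5.0],
        }
    )


def brute_force_patches(grid: np.ndarray, connectivity: int) -> int:
    """Independent flood-fill patch counter (stack-based, pure python)."""
    nrows, ncols = grid.shape
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(grid, dtype=bool)
    count = 0
    for r in range(nrows):
        for c in range(ncols):
            if grid[r, c] != 1 or seen[r, c]:
                continue
            count += 1
            stack = [(r, c)]
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                for dr, dc in offsets:
                    nr, nc = rr + dr, cc + dc
                    if 0 <= nr < nrows and 0 <= nc < ncols:
                        if grid[nr, nc] == 1 and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
    return count
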