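"""Shared fixtures: the simulated gradients every stage is exercised on."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from taunich.simulate import default_scenario, simulate_gradient


@pytest.fixture(scope="session")
def default_gradient():
    """The shipped study conditions: 60 taxa, 49 tau values, depth 50,000."""
    return simulate_gradient(default_scenario(0))


@pytest.fixture(scope="session")
def small_gradient():
    """Thinned gradient (13 chemostats, depth 5,000) for fast structural tests."""
    base = default_scenario(0)
    scenario = replace(base, tau_grid=base.tau_grid[::4], read_depth=5_000)
    return simulate_gradient(scenario)


@pytest.fixture()
def toy_counts():
    """Tiny hand-checkable count table (4 taxa x 5 chemostats)."""
    return pd.DataFrame(
        [
            [10, 8, 5, 2, 0],
            [0, 2, 5, 8, 10],
            [4, 4, 4, 4, 4],
            [9, 0, 0, 0, 1],
        ],
        index=["left", "right", "flat", "sparse"],
        columns=[f"c{i}" for i in range(5)],
        dtype=np.int64,
    )
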