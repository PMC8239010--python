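"""Shared fixtures: small synthetic screens reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import euscreen as es
from euscreen.synthetic import SimulationConfig, simulate_edu_plate, simulate_screen


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    # two plates at reduced cell counts: fast, but still enough cells per
    # well for stable medians and valley finding
    return SimulationConfig(n_plates=2, cells_per_well_mean=60.0, seed=11)


@pytest.fixture(scope="session")
def screen(small_config):
    cells, design, truth = simulate_screen(small_config)
    return cells, design, truth


@pytest.fixture(scope="session")
def edu_plate(small_config):
    cells, design, truth = simulate_edu_plate(small_config)
    return cells, design, truth


@pytest.fixture(scope="session")
def two_screens():
    return es.simulate_two_screens(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_cells(values: dict, n: int | None = None) -> pd.DataFrame:
    """Minimal hand-built cell table for arithmetic unit tests."""
    n = n or max(len(np.atleast_1d(v)) for v in values.values())
    base = {
        "plate": 1, "row": 2, "col": 3, "site": 1,
        "cell_id": np.arange(1, n + 1),
        "is_border": False, "is_mitotic_or_apoptotic": False,
        "is_missegmented": False,
    }
    base.update(values)
    df = pd.DataFrame(base)
    if "well_name" not in df.columns:
        df["well_name"] = [
            f"{'ABCDEFGHIJKLMNOP'[r-1]}{c:02d}"
            for r, c in zip(np.atleast_1d(df['row']), np.atleast_1d(df['col']))
        ]
    return df
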