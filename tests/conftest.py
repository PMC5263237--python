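import numpy as np
import pandas as pd
import pytest

from microturn.synthetic_population import SNAPSHOT_COLUMNS, SimulationConfig


@pytest.fixture
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture
def small_config():
    """Cheap single-FOV configuration for fast unit tests."""
    return SimulationConfig(n_fov=1, initial_cells_per_fov=30, n_days=6, seed=7)


def make_table(rows, fov=None):
    """Build a snapshot table from (day, cell_id, parent_id, x, y, z, event,
    labels) tuples."""
    df = pd.DataFrame(rows, columns=SNAPSHOT_COLUMNS)
    df["day"] = df["day"].astype(int)
    for c in ("x_um", "y_um", "z_um"):
        df[c] = df[c].astype(float)
    if fov is not None:
        df.insert(0, "fov", fov)
    return df


def static_population(n_cells, n_days, spacing=30.0, events=()):
    """n_cells immobile cells on a line observed for n_days; ``events`` is a
    list of (cell_index, day, event) overrides."""
    overrides = {(c, d): e for c, d, e in events}
    rows = []
    for day in range(n_days):
        for i in range(n_cells):
            event = overrides.get((i, day), "none")
            if any(c == i and d < day and e == "died" for (c, d), e in overrides.items()):
                continue  # dead cells stay dead
            rows.append((day, f"c{i:03d}", "", i * spacing, 0.0, 0.0, event, ""))
    return make_table(rows)
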