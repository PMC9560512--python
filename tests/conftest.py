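import numpy as np
import pandas as pd
import pytest

from colonyfit import PlateSimConfig, simulate_plate


@pytest.fixture(scope="session")
def six_strain_plate():
    """One simulated trimmed 384 plate: 2 ancestors + 4 evolved strains."""
    cfg = PlateSimConfig(
        strain_s={"anc1": 0.0, "anc2": 0.0, "ev000": 0.0, "ev001": 0.01,
                  "ev005": 0.05, "ev010": 0.10},
        sigma=0.05, trimmed=True, seed=42,
    )
    layout, obs = simulate_plate(cfg)
    return cfg, layout, obs


def long_table(records):
    """Small long-format colony table from (day, row, col, strain, size) tuples."""
    rows = [
        {"plate_id": "p1", "condition": "CM", "day": d, "row": r, "col": c,
         "strain": s, "replicate": 1, "size_px": float(size), "status": "OK",
         "zero_flag": None}
        for d, r, c, s, size in records
    ]
    return pd.DataFrame(rows)
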