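import numpy as np
import pandas as pd
import pytest

from polyqhcs import screen, synthdata


@pytest.fixture(scope="session")
def small_screen():
    """Small null screen (no planted effects) shared by read-only tests."""
    cfg = synthdata.ScreenSimConfig(n_compounds=120, seed=11)
    return synthdata.simulate_screen(cfg)


@pytest.fixture(scope="session")
def normalized_small_screen(small_screen):
    plates, _ = small_screen
    return screen.normalize_plates(plates.wells)


def make_plate(counts_by_role, plate_id="P1"):
    """Hand-built single-plate table: {role: [counts...]} -> tidy wells."""
    rows = []
    col = 1
    for role, counts in counts_by_role.items():
        for i, c in enumerate(counts):
            rows.append({
                "plate_id": plate_id, "layout_id": "L1", "replicate": 1,
                "row": 2, "col": col, "well": f"B{col:02d}", "role": role,
                "compound_id": f"C{i + 1:04d}" if role == "compound" else "",
                "dose_uM": 1.0 if role == "compound" else 0.0,
                "nuclei_count": c, "is_edge": False,
            })
            col += 1
    return pd.DataFrame(rows)
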