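import numpy as np
import pandas as pd
import pytest

from slme import LongDataset, build_sector_grid


@pytest.fixture(scope="session")
def grid():
    return build_sector_grid()


def make_long(rows):
    """rows: (patient, eye, sector, thickness, extra-dict)."""
    recs = []
    for r in rows:
        base = {"patient_id": r[0], "eye_id": r[1], "sector": r[2],
                "thickness": r[3]}
        if len(r) > 4:
            base.update(r[4])
        recs.append(base)
    return LongDataset(pd.DataFrame(recs))


@pytest.fixture
def one_eye_nine_sectors(grid):
    """One patient, one eye, all nine sectors, deterministic thicknesses."""
    rng = np.random.default_rng(0)
    return make_long([
        ("P1", "OD", s, 280 + 5 * i + rng.normal())
        for i, s in enumerate(grid.sector_ids)
    ])
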