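import io

import numpy as np
import pandas as pd
import pytest

from pfnorm.data_model import LongTable, derive_pltem
from pfnorm.synthetic import default_config, generate_study

TINY_CSV = """patient,timepoint,attribute,value,unit
P01,S1,PlatCt,320,10^9/L
P01,S1,MCF EXTEM,61,mm
P01,S1,MCF FIBTEM,14,mm
"""


@pytest.fixture
def tiny_csv():
    return io.StringIO(TINY_CSV)


@pytest.fixture
def tiny_table():
    return LongTable(
        pd.DataFrame(
            {
                "patient_id": ["P01", "P01", "P01", "P02", "P02", "P02"],
                "timepoint": ["S1", "S2", "S1", "S1", "S2", "S2"],
                "attribute": ["PlatCt", "PlatCt", "MCF EXTEM", "PlatCt", "PlatCt", "MCF EXTEM"],
                "value": [320.0, 180.0, 61.0, 410.0, 230.0, 55.0],
            }
        )
    )


@pytest.fixture(scope="session")
def demo_study():
    """Seeded default study (the composite pipeline's demo input)."""
    table, report = generate_study(default_config(seed=42))
    return table, report


@pytest.fixture(scope="session")
def demo_derived(demo_study):
    table, _ = demo_study
    return derive_pltem(table, parameters=("MCF",))


def random_long_table(rng: np.random.Generator) -> LongTable:
    """Small random valid LongTable (used by partition/pivot stress tests)."""
    n_p = rng.integers(1, 6)
    n_t = rng.integers(1, 4)
    n_a = rng.integers(1, 5)
    patients = [f"P{i}" for i in range(n_p)]
    tps = [f"S{i + 1}" for i in range(n_t)]
    attrs = [f"attr{i}" for i in range(n_a)]
    rows = []
    for p in patients:
        for t in tps:
            for a in attrs:
                if rng.random() < 0.8:
                    rows.append((p, t, a, float(np.round(rng.normal(50, 20), 3))))
    if not rows:
        rows.append((patients[0], tps[0], attrs[0], 1.0))
    df = pd.DataFrame(rows, columns=["patient_id", "timepoint", "attribute", "value"])
    return LongTable(df, timepoint_order=tps)
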