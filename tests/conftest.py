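import numpy as np
import pandas as pd
import pytest

from aimpanel.io_formats import MISSING, GenotypeTable
from aimpanel.synthetic_data import make_world_fixture

REFERENCE_N = 509  # diploid sample size behind the published panel statistics


@pytest.fixture(scope="session")
def reference_stats() -> pd.DataFrame:
    """Published per-locus statistics of the 39-locus panel (509 individuals)."""
    from importlib.resources import files

    path = files("aimpanel").joinpath("data/panel_reference_stats.csv")
    return pd.read_csv(str(path), index_col="locus")


@pytest.fixture(scope="session")
def world():
    """Mid-sized five-continent world fixture shared across tests."""
    return make_world_fixture(seed=11, n_per_group=60, L=38)


@pytest.fixture
def tiny_table() -> GenotypeTable:
    """Two populations, four loci, one missing call."""
    dosage = np.array([
        [2, 1, 0, 2],
        [2, 2, 1, 1],
        [0, 0, 2, MISSING],
        [1, 0, 2, 0],
    ])
    return GenotypeTable(["a1", "a2", "b1", "b2"], ["A", "A", "B", "B"],
                         ["L1", "L2", "L3", "L4"], dosage)


def two_pop_table(counts_a, counts_b, locus: str = "L1") -> GenotypeTable:
    """Build a one-locus table realizing given (n_II, n_ID, n_DD) per population."""
    rows, labels, ids = [], [], []
    for pop, counts in (("A", counts_a), ("B", counts_b)):
        for dosage, k in zip((2, 1, 0), counts):
            for _ in range(k):
                ids.append(f"{pop}{len(ids)}")
                labels.append(pop)
                rows.append([dosage])
    return GenotypeTable(ids, labels, [locus], np.array(rows))
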