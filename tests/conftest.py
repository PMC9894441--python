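import numpy as np
import pytest

from jttrend import GenotypeTable, get_fixture


@pytest.fixture
def rs2398162() -> GenotypeTable:
    """Hypertension worked example: 1940 cases, 2923 controls."""
    return get_fixture("rs2398162")


def random_integer_tables(n_tables: int, max_cell: int, seed: int,
                          min_per_row: int = 1) -> list[GenotypeTable]:
    """Random valid integer tables with at least one case and one control."""
    rng = np.random.default_rng(seed)
    tables = []
    while len(tables) < n_tables:
        r = rng.integers(0, max_cell + 1, size=3)
        s = rng.integers(0, max_cell + 1, size=3)
        if r.sum() < min_per_row or s.sum() < min_per_row:
            continue
        # need at least two non-empty genotype groups for the trend tests
        if np.count_nonzero(r + s) < 2:
            continue
        tables.append(GenotypeTable(tuple(int(v) for v in r), tuple(int(v) for v in s)))
    return tables
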