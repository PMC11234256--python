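import numpy as np
import pandas as pd
import pytest

from apmstats.model import AbundanceMatrix
from apmstats.simulate import default_layout


@pytest.fixture(scope="session")
def layout9():
    """The standard 3 WT + 3 variant + 3 negative-control design."""
    return default_layout(3)


def make_matrix(rows: dict[str, list[float]], bait_id: str = "BAIT") -> AbundanceMatrix:
    """Build an AbundanceMatrix from 9-value rows (WT-1..3, VAR-1..3, CTRL-1..3).

    Use np.nan for missing cells.  A bait row at level 1000 in the
    experimental channels is added automatically if absent.
    """
    cols = ["WT-1", "WT-2", "WT-3", "VAR-1", "VAR-2", "VAR-3",
            "CTRL-1", "CTRL-2", "CTRL-3"]
    rows = dict(rows)
    if bait_id not in rows:
        rows[bait_id] = [1000.0] * 6 + [10.0] * 3
    data = pd.DataFrame.from_dict(rows, orient="index", columns=cols).astype(float)
    return AbundanceMatrix(data=data, bait_id=bait_id)


@pytest.fixture
def make_matrix_fn():
    return make_matrix
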