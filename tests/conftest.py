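import numpy as np
import pandas as pd
import pytest

from metimpute import AbundanceTable


@pytest.fixture
def tiny_table() -> AbundanceTable:
    """4 samples x 3 metabolites, raw scale, one missing cell."""
    df = pd.DataFrame(
        {
            "m1": [100.0, 200.0, 150.0, 120.0],
            "m2": [10.0, np.nan, 30.0, 20.0],
            "m3": [1.0, 2.0, 3.0, 4.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return AbundanceTable(df, scale="raw")


@pytest.fixture
def complete_log_table() -> AbundanceTable:
    """8 samples x 5 metabolites on the log10 scale, no missing cells."""
    rng = np.random.default_rng(7)
    vals = rng.normal(5.0, 0.5, size=(8, 5))
    df = pd.DataFrame(
        vals,
        index=[f"s{i}" for i in range(8)],
        columns=[f"m{j}" for j in range(5)],
    )
    return AbundanceTable(df, scale="log10")


def make_log_table(vals: np.ndarray) -> AbundanceTable:
    vals = np.asarray(vals, dtype=float)
    df = pd.DataFrame(
        vals,
        index=[f"s{i}" for i in range(vals.shape[0])],
        columns=[f"m{j}" for j in range(vals.shape[1])],
    )
    return AbundanceTable(df, scale="log10")
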