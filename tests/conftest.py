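import numpy as np
import pandas as pd
import pytest

from bfsig.io import ExpressionMatrix, ResponseTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_expr(rng):
    vals = rng.uniform(0.5, 5.0, size=(10, 6))
    return ExpressionMatrix(vals, [f"G{i}" for i in range(10)],
                            [f"S{j}" for j in range(6)])


@pytest.fixture
def response_table():
    rows = [
        ("s1", "P1", 1, "venetoclax", 0.5, np.nan),
        ("s2", "P1", 2, "venetoclax", 0.8, np.nan),
        ("s3", "P2", 1, "venetoclax", 12.0, np.nan),
        ("s4", "P3", 1, "venetoclax", 5.0, np.nan),
        ("s5", "P4", 1, "venetoclax", 10.0, np.nan),
        ("s6", "P4", 2, "venetoclax", 1.0, np.nan),
    ]
    return ResponseTable(pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "time_point", "drug",
                       "ic50_uM", "auc"]))
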