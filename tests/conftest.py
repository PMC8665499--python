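import numpy as np
import pandas as pd
import pytest

from refstab import CtMatrix, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_ct():
    """4 genes x 6 samples, mild noise, no structure."""
    rng = np.random.default_rng(7)
    vals = 20.0 + rng.normal(0, 0.8, size=(4, 6))
    return pd.DataFrame(vals, index=["g1", "g2", "g3", "g4"],
                        columns=[f"s{i}" for i in range(6)])


@pytest.fixture
def grouped_ct():
    """6 genes x 12 samples in 3 groups of 4, with metadata."""
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(12)]
    vals = 22.0 + rng.normal(0, 0.5, size=(6, 12))
    meta = pd.DataFrame(
        {"class_label": ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
         "material": "tissue"},
        index=pd.Index(samples, name="sample"),
    )
    return CtMatrix(pd.DataFrame(vals, index=genes, columns=samples), meta=meta)


@pytest.fixture
def small_expr():
    rng = np.random.default_rng(3)
    vals = np.abs(rng.lognormal(np.log(30), 0.3, size=(8, 50)))
    return ExpressionMatrix(pd.DataFrame(
        vals, index=[f"g{i}" for i in range(8)],
        columns=[f"p{i}" for i in range(50)]))
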