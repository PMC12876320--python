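import numpy as np
import pandas as pd
import pytest

from hemivox.expression_io import CountMatrix
from hemivox.synthetic_data import ExpressionSimSpec, simulate_expression


@pytest.fixture
def toy_counts() -> CountMatrix:
    rng = np.random.default_rng(0)
    counts = rng.poisson(50, size=(10, 6))
    return CountMatrix(
        [f"g{i}" for i in range(10)], [f"s{j}" for j in range(6)], counts
    )


@pytest.fixture
def small_cohort():
    """5 donors x 2 areas x both hemispheres, one strongly lateralized gene."""
    spec = ExpressionSimSpec(
        n_genes=80,
        n_donors=5,
        areas=["BA44", "BA22"],
        lateralized_genes={"gene00001": ("BA44", 2.0)},
        seed=42,
    )
    return simulate_expression(spec)


def make_meta(samples):
    """Metadata table from (sample_id, donor, hemisphere, area) tuples."""
    rows = [
        {
            "sample_id": s,
            "donor": d,
            "hemisphere": h,
            "area": a,
            "sex": "M",
            "age": 70,
            "handedness": "R",
            "family_history": "no",
            "language_disorder": "no",
        }
        for s, d, h, a in samples
    ]
    return pd.DataFrame(rows)
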