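import numpy as np
import pandas as pd
import pytest

from tmescope import (
    ExpressionMatrix,
    SimulationConfig,
    make_signature_matrix,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_signature():
    return make_signature_matrix(5, 20, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_signature):
    cfg = SimulationConfig(n_samples=120, seed=42)
    expr, clinical, truth = simulate_cohort(cfg, small_signature)
    return {"cfg": cfg, "expr": expr, "clinical": clinical, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_expr(values, genes=None, samples=None, scale="linear"):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), scale)
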