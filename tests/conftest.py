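import numpy as np
import pandas as pd
import pytest

from adiposcreen.prep import CountMatrix
from adiposcreen.synth import SimConfig, simulate_study


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def toy_counts():
    """5 genes x 4 samples with known structure; sample S1 = 2 x S0."""
    vals = pd.DataFrame(
        {
            "S0": [100, 200, 50, 400, 250],
            "S1": [200, 400, 100, 800, 500],
            "S2": [120, 180, 60, 380, 260],
            "S3": [90, 210, 40, 420, 240],
        },
        index=[f"g{i}" for i in range(5)],
    )
    return CountMatrix(vals)


@pytest.fixture(scope="session")
def small_bundle():
    """A small complete study bundle shared across read-only tests."""
    cfg = SimConfig(
        n_samples=120,
        n_genes_adipose=300,
        n_genes_liver=300,
        n_shared_genes=240,
        n_variants=30,
        seed=42,
    )
    return simulate_study(cfg)
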