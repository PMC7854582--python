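import numpy as np
import pandas as pd
import pytest

import hoxcode as hx


@pytest.fixture(scope="session")
def gene_set():
    return hx.hox_gene_set()


@pytest.fixture(scope="session")
def default_cohort():
    """Default 24-tissue, 8-samples-per-tissue synthetic cohort (seed 0)."""
    cfg = hx.SyntheticConfig(seed=0)
    m, meta, truth = hx.generate_cohort(cfg)
    return m, meta, truth


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 samples with easily hand-checked values."""
    return pd.DataFrame(
        {
            "s1": [0.0, 1.0, 3.0],
            "s2": [1.0, 5.0, 7.0],
            "s3": [3.0, 100.0, 0.0],
            "s4": [7.0, 2.0, 1.0],
        },
        index=pd.Index(["HOXA1", "HOXB13", "HOXD9"], name="gene"),
    )


def random_expression(seed, n_genes=None, n_samples=None):
    """Random valid expression matrix on a subset of HOX symbols plus fillers."""
    rng = np.random.default_rng(seed)
    n_genes = n_genes or rng.integers(2, 30)
    n_samples = n_samples or rng.integers(1, 12)
    genes = [f"G{seed}X{i}" for i in range(n_genes)]
    values = rng.uniform(0, 1e4, size=(n_genes, n_samples))
    # sprinkle in exact zeros and tiny values to stress formatting
    values[rng.random(values.shape) < 0.1] = 0.0
    return pd.DataFrame(
        values,
        index=pd.Index(genes, name="gene"),
        columns=[f"samp{j}" for j in range(n_samples)],
    )
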