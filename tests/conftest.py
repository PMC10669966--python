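import numpy as np
import pandas as pd
import pytest

from lpsdeg.matrix import CountMatrix


@pytest.fixture
def small_matrix() -> CountMatrix:
    """30 genes x 12 samples in two groups, moderate NB counts."""
    rng = np.random.default_rng(123)
    counts = rng.negative_binomial(10, 10 / (10 + 50.0), size=(30, 12))
    genes = [f"G{i:03d}" for i in range(30)]
    samples = [f"S{i:02d}" for i in range(12)]
    groups = pd.Series(["A"] * 6 + ["B"] * 6, index=samples)
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), groups)


def random_count_matrix(seed: int, n_genes: int = 80, n_samples: int = 20) -> CountMatrix:
    """Random matrix with uneven library sizes and three groups."""
    rng = np.random.default_rng(seed)
    mu = np.outer(
        np.exp(rng.uniform(0, 5, n_genes)), rng.uniform(0.5, 2.0, n_samples)
    )
    counts = rng.poisson(mu)
    genes = [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"S{i:02d}" for i in range(n_samples)]
    labels = rng.choice(["A", "B", "C"], size=n_samples)
    # ensure every group occurs at least twice
    labels[:6] = ["A", "A", "B", "B", "C", "C"]
    groups = pd.Series(labels, index=samples)
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), groups)
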