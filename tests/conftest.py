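import numpy as np
import pandas as pd
import pytest

from ddcpredict.io import ExpressionMatrix


@pytest.fixture
def small_matrix():
    """3-gene x 4-sample matrix with two groups."""
    data = pd.DataFrame(
        np.array([[1.0, 2.0, 5.0, 6.0],
                  [4.0, 3.0, 1.0, 0.5],
                  [2.0, 2.5, 2.1, 2.4]]),
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    labels = {"s1": "LN", "s2": "LN", "s3": "control", "s4": "control"}
    return ExpressionMatrix("toy", "blood", data, labels)


@pytest.fixture
def two_group_matrix():
    """Well-separated 40-gene case/control matrix (deterministic)."""
    rng = np.random.default_rng(7)
    n_genes, n_case, n_ctrl = 40, 8, 8
    genes = [f"g{i:02d}" for i in range(n_genes)]
    samples = [f"c{i}" for i in range(n_case)] + [f"h{i}" for i in range(n_ctrl)]
    gene_mean = rng.normal(7, 2, size=(n_genes, 1))  # shared per-gene baseline
    base = gene_mean + rng.normal(0, 0.5, size=(n_genes, n_case + n_ctrl))
    base[:20, :n_case] += 5.0  # first 20 genes strongly up in cases
    labels = {s: ("LN" if s.startswith("c") else "control") for s in samples}
    return ExpressionMatrix("sep", "blood", pd.DataFrame(base, index=genes, columns=samples), labels)
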