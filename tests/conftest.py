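import numpy as np
import pandas as pd
import pytest

from coexshift.coexpress import PairCoexpression
from coexshift.expression_io import ExpressionMatrix


def make_matrix(values: np.ndarray, n_disease: int, n_normal: int,
                genes=None) -> ExpressionMatrix:
    """Wrap a genes-by-samples array with disease-first sample labels."""
    g, s = values.shape
    assert s == n_disease + n_normal
    genes = genes or [f"G{k:03d}" for k in range(g)]
    samples = [f"D{k}" for k in range(n_disease)] + [f"N{k}" for k in range(n_normal)]
    groups = pd.Series(["disease"] * n_disease + ["normal"] * n_normal, index=samples)
    return ExpressionMatrix(values=pd.DataFrame(values, index=genes, columns=samples),
                            groups=groups)


def make_pc(c_disease, c_normal, genes=None) -> PairCoexpression:
    """Build a PairCoexpression directly from per-pair value vectors."""
    c_d = np.asarray(c_disease, dtype=float)
    c_n = np.asarray(c_normal, dtype=float)
    n_pairs = len(c_d)
    # smallest g with g(g-1)/2 >= n_pairs; pad with midpoint values
    g = 2
    while g * (g - 1) // 2 < n_pairs:
        g += 1
    total = g * (g - 1) // 2
    pad = total - n_pairs
    if pad:
        c_d = np.concatenate([c_d, np.full(pad, 0.5)])
        c_n = np.concatenate([c_n, np.full(pad, 0.5)])
    genes = genes or [f"G{k:03d}" for k in range(g)]
    iu, ju = np.triu_indices(g, k=1)
    return PairCoexpression(genes=genes, pair_index=np.column_stack([iu, ju]),
                            c_disease=c_d, c_normal=c_n)


@pytest.fixture
def rng():
    return np.random.default_rng(20150415)


@pytest.fixture
def random_matrix(rng):
    """12 genes x (6 disease + 5 normal) of smooth random expression."""
    return make_matrix(rng.normal(8.0, 1.0, size=(12, 11)), 6, 5)
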