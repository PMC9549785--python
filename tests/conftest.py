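import numpy as np
import pytest

from spotdecon import CellTypeAnnotation, FixtureSpec, GeneCountMatrix, generate_reference


@pytest.fixture
def tiny_reference():
    """3 types x 4 cells each, 6 genes; g0/g1/g2 mark types A/B/C."""
    rng = np.random.default_rng(42)
    K, n_per, G = 3, 4, 6
    counts = rng.poisson(1.0, size=(K * n_per, G)).astype(float)
    for t in range(K):
        counts[t * n_per : (t + 1) * n_per, t] += 20
    counts += 0.01 * rng.random(counts.shape)  # break zero within-group variance
    obs = [f"c{i}" for i in range(K * n_per)]
    genes = [f"g{j}" for j in range(G)]
    labels = ["A"] * n_per + ["B"] * n_per + ["C"] * n_per
    matrix = GeneCountMatrix(counts, obs, genes)
    annotation = CellTypeAnnotation(dict(zip(obs, labels)), ["A", "B", "C"])
    return matrix, annotation


@pytest.fixture(scope="session")
def separable_reference():
    """Default synthetic reference: K=5, disjoint marker blocks, fold 10."""
    spec = FixtureSpec(seed=7)
    matrix, annotation = generate_reference(spec)
    return spec, matrix, annotation
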