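import numpy as np
import pytest

from abds.matrix import LINEAR, LOG2, GroupLabels, OmicsMatrix


@pytest.fixture
def two_group_labels():
    return GroupLabels.from_pairs([("s1", "A"), ("s2", "A"), ("s3", "B"), ("s4", "B")])


@pytest.fixture
def small_log_matrix():
    """4 genes x 4 samples, log2 space, two masked cells."""
    vals = np.array([
        [4.0, 6.0, 5.0, 7.0],
        [3.0, 3.5, 8.0, 8.5],
        [5.0, 0.0, 6.0, 6.5],   # masked at (2, 1)
        [2.0, 2.5, 0.0, 3.0],   # masked at (3, 2)
    ])
    mask = np.zeros((4, 4), dtype=bool)
    mask[2, 1] = True
    mask[3, 2] = True
    return OmicsMatrix(vals, mask, LOG2,
                       ["g1", "g2", "g3", "g4"], ["s1", "s2", "s3", "s4"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_masked_matrix(rng, n_genes=30, n_samples=12, miss=0.2, space=LOG2):
    vals = rng.normal(8.0, 2.0, size=(n_genes, n_samples))
    if space == LINEAR:
        vals = np.abs(vals)
    mask = rng.random((n_genes, n_samples)) < miss
    # keep at least two observed values per gene
    for i in range(n_genes):
        if mask[i].sum() > n_samples - 2:
            mask[i, :] = False
    return OmicsMatrix(vals, mask, space,
                       [f"g{i}" for i in range(n_genes)],
                       [f"s{j}" for j in range(n_samples)])
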