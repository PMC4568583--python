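import numpy as np
import pytest

from epichi import GwasMatrix


def pearson_oracle(counts):
    """Independent Pearson chi-square: explicit O/E double loop."""
    counts = np.asarray(counts, dtype=float)
    n_rows, n_cols = counts.shape
    total = counts.sum()
    stat = 0.0
    for r in range(n_rows):
        for c in range(n_cols):
            expected = counts[r].sum() * counts[:, c].sum() / total
            stat += (counts[r, c] - expected) ** 2 / expected
    return stat


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_gwas(rng):
    """60 subjects x 20 SNPs of independent genotypes, labels unrelated."""
    G = rng.integers(0, 3, size=(60, 20)).astype(np.int8)
    return GwasMatrix(genotypes=G, n_cases=30)
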