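import numpy as np
import pytest

from fastbaps import Alignment, SyntheticConfig, build_snp_matrix, simulate


@pytest.fixture
def tiny_aln():
    """Three sequences, one variable column (the last: T/A/A)."""
    return Alignment(labels=["s1", "s2", "s3"], sequences=["ACGT", "ACGA", "ACGA"])


@pytest.fixture
def tiny_matrix(tiny_aln):
    return build_snp_matrix(tiny_aln)


@pytest.fixture
def two_group_aln():
    """Two groups of identical sequences separated by many fixed differences."""
    a = "ACGTACGTACGTACGTACGT"
    b = "TGCATGCATGCATGCATGCA"
    labels = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
    return Alignment(labels=labels, sequences=[a] * 5 + [b] * 5)


@pytest.fixture
def five_deme_data():
    """Well-separated simulated demes used by several end-to-end tests."""
    return simulate(SyntheticConfig(k_demes=5, n_per_deme=12, n_loci=150, seed=11))


def random_alignment(rng, n, length, missing_rate=0.0):
    """Unstructured random alignment (i.i.d. uniform bases, optional gaps)."""
    chars = np.array(list("ACGT"))
    seqs = chars[rng.integers(0, 4, size=(n, length))]
    if missing_rate > 0:
        mask = rng.random((n, length)) < missing_rate
        seqs[mask] = np.array(["-", "N", "R"])[rng.integers(0, 3, size=mask.sum())]
    return Alignment(
        labels=[f"s{i}" for i in range(n)],
        sequences=["".join(row) for row in seqs],
    )
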