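"""Fast initial clustering that seeds the Bayesian agglomeration.

A pairwise SNP mismatch distance matrix is clustered with Ward's
minimum-variance linkage and the resulting hierarchy is cut into
K_init small clusters.  For very large sample sizes the quadratic
distance matrix is avoided by clustering the leading principal
components of the one-hot allele matrix instead; on well-separated
data the two routes give near-identical initial partitions because the
initial cut only matters at the lowest levels of the hierarchy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .alignment import SnpCountMatrix

#: Sample-count threshold above which the PCA route is used by default.
DEFAULT_PCA_THRESHOLD = 10_000
#: Number of principal components retained on the PCA route.
DEFAULT_N_COMPONENTS = 50
#: Cap on the default number of initial clusters.
DEFAULT_K_INIT_CAP = 100
#: Seed for the randomized truncated-SVD solver (reproducibility).
DEFAULT_PCA_SEED = 42


@dataclass
class InitialClustering:
    """A Ward hierarchy over samples plus its cut into k_init groups."""

    hierarchy: np.ndarray  # scipy linkage matrix, (n-1, 4)
    k_init: int
    assignment: np.ndarray  # sample -> initial-cluster index, 0-based
    method: str  # "distance" or "pca"

    @property
    def n(self) -> int:
        return self.hierarchy.shape[0] + 1

    def groups(self) -> list[np.ndarray]:
        """Member index arrays of the k_init initial clusters."""
        return [
            np.nonzero(self.assignment == g)[0] for g in range(self.k_init)
        ]


def default_k_init(n: int) -> int:
    """Default K_init: much larger than any plausible K, capped."""
    return min(math.ceil(n / 4), DEFAULT_K_INIT_CAP, n)


def snp_distance_matrix(m: SnpCountMatrix) -> np.ndarray:
    """Pairwise SNP mismatch counts over retained loci.

    Entry (i, j) is the number of loci where both samples carry a
    countable base and the bases differ; loci where either sample is
    missing contribute nothing.
    """
    one_hot = m.one_hot()
    matches = np.asarray((one_hot @ one_hot.T).todense(), dtype=np.float64)
    nonmissing = 1.0 - np.asarray(m.missing.todense(), dtype=np.float64)
    comparable = nonmissing @ nonmissing.T
    d = comparable - matches
    np.fill_diagonal(d, 0.0)
    return d


def ward_hierarchy(data: np.ndarray, *, is_distance: bool | None = None) -> np.ndarray:
    """Ward minimum-variance linkage over samples.

    ``data`` is either a square symmetric distance matrix or an
    (n, p) feature matrix; the ambiguity is resolved by shape unless
    ``is_distance`` is given.  Deterministic given its input.
    """
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in clustering input")
    if is_distance is None:
        is_distance = (
            data.ndim == 2
            and data.shape[0] == data.shape[1]
            and np.allclose(data, data.T)
            and np.allclose(np.diag(data), 0.0)
        )
    if is_distance:
        return sch.linkage(squareform(data, checks=False), method="ward")
    return sch.linkage(data, method="ward")


def pca_features(
    m: SnpCountMatrix,
    n_components: int = DEFAULT_N_COMPONENTS,
    seed: int = DEFAULT_PCA_SEED,
) -> np.ndarray:
    """Centered principal-component scores of the one-hot allele matrix.

    ``n_components`` is silently capped at min(n_samples - 1, columns).
    """
    x = np.asarray(m.one_hot().todense(), dtype=np.float64)
    cap = max(1, min(m.n_samples - 1, x.shape[1]))
    pca = PCA(n_components=min(n_components, cap), random_state=seed)
    return pca.fit_transform(x)


def cut_to_k(hierarchy: np.ndarray, k: int) -> np.ndarray:
    """Cut a linkage hierarchy into exactly k groups (undo last k-1 merges).

    Returns a 0-based assignment array; group numbering follows scipy's
    ``cut_tree`` (order of first appearance).
    """
    n = hierarchy.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    return sch.cut_tree(hierarchy, n_clusters=k).ravel()


def initial_clustering(
    m: SnpCountMatrix,
    k_init: int | None = None,
    *,
    pca_threshold: int = DEFAULT_PCA_THRESHOLD,
    n_components: int = DEFAULT_N_COMPONENTS,
    force_pca: bool = False,
    pca_seed: int = DEFAULT_PCA_SEED,
) -> InitialClustering:
    """Build the Ward hierarchy and cut it into K_init initial clusters."""
    n = m.n_samples
    if k_init is None:
        k_init = default_k_init(n)
    if not 1 <= k_init <= n:
        raise ValueError(f"k_init={k_init} out of range [1, {n}]")
    use_pca = force_pca or n > pca_threshold
    if use_pca:
        features = pca_features(m, n_components=n_components, seed=pca_seed)
        hierarchy = ward_hierarchy(features, is_distance=False)
        method = "pca"
    else:
        hierarchy = ward_hierarchy(snp_distance_matrix(m), is_distance=True)
        method = "distance"
    assignment = cut_to_k(hierarchy, k_init)
    return InitialClustering(
        hierarchy=hierarchy, k_init=k_init, assignment=assignment, method=method
    )
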