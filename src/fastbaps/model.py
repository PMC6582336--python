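"""Probabilistic core of the Dirichlet-process mixture approximation.

Everything here works in natural-log space.  The component model for a
cluster is multinomial with a per-locus Dirichlet prior on the allele
frequencies, so the marginal likelihood of a cluster's allele counts is
a product of gamma-function ratios, evaluated with ``gammaln``.  The
prior probability of a merge, pi_k, is accumulated bottom-up through
the d-recursion of Bayesian hierarchical clustering and depends only on
the Dirichlet-process concentration alpha and the merge structure.

alpha is fixed at 1 by default throughout the package: the pi_k
recursion is dominated by the factorial in the number of samples under
a node, so the concentration has almost no influence on realistic
datasets.  An expert-level argument exposes it for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .alignment import SnpCountMatrix

#: Default Dirichlet-process concentration.
DEFAULT_ALPHA = 1.0

#: Recognised prior kinds.
PRIOR_KINDS = ("baps", "symmetric", "bhc_counts")


def log1mexp(x: float) -> float:
    """Stable log(1 - exp(x)) for x <= 0; returns -inf at x == 0."""
    if x > 0:
        raise ValueError("log1mexp requires x <= 0")
    if x == 0.0:
        return -math.inf
    if x > -math.log(2.0):
        return math.log(-math.expm1(x))
    return math.log1p(-math.exp(x))


@dataclass
class DirichletPrior:
    """Per-locus, per-allele Dirichlet hyperparameters with a scale.

    kind
        ``baps``      — pre-scale beta_jl = 1 / N_A(j) (non-informative),
        ``symmetric`` — pre-scale beta_jl = 1,
        ``bhc_counts``— pre-scale proportional to the global allele
        counts at each locus, normalised so each locus's hyperparameters
        sum to N_A(j) (comparable magnitude to the symmetric prior).
    beta
        Flat positive array over (locus, allele) columns, aligned with
        the count matrix's ``offsets``; already multiplied by ``scale``.
    """

    kind: str
    beta: np.ndarray
    offsets: np.ndarray
    scale: float = 1.0
    # cached pieces of the marginal-likelihood formula
    _gl_beta: np.ndarray = field(init=False, repr=False)
    _beta_locus_sum: np.ndarray = field(init=False, repr=False)
    _gl_beta_locus_sum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if np.any(self.beta <= 0) or not np.all(np.isfinite(self.beta)):
            raise ValueError("all hyperparameters beta must be positive")
        self._gl_beta = gammaln(self.beta)
        self._beta_locus_sum = np.add.reduceat(self.beta, self.offsets[:-1])
        self._gl_beta_locus_sum = gammaln(self._beta_locus_sum)


def make_prior(m: SnpCountMatrix, kind: str, scale: float = 1.0) -> DirichletPrior:
    """Build a DirichletPrior of the given kind for a count matrix."""
    if kind not in PRIOR_KINDS:
        raise ValueError(f"unknown prior kind {kind!r}; expected one of {PRIOR_KINDS}")
    if scale <= 0:
        raise ValueError("prior scale must be positive")
    n_alleles = m.n_alleles
    if kind == "baps":
        beta = np.repeat(1.0 / n_alleles, n_alleles)
    elif kind == "symmetric":
        beta = np.ones(m.n_columns)
    else:  # bhc_counts
        total = m.cluster_counts(np.arange(m.n_samples))
        locus_tot = np.add.reduceat(total, m.offsets[:-1])
        beta = total / np.repeat(locus_tot, n_alleles) * np.repeat(
            n_alleles.astype(float), n_alleles
        )
        # a globally absent allele cannot occur in any cluster, but the
        # count matrix only stores observed alleles, so beta stays > 0
        beta = np.maximum(beta, 1e-12)
    return DirichletPrior(kind=kind, beta=beta * scale, offsets=m.offsets, scale=scale)


def log_marginal_h1(counts: np.ndarray, prior: DirichletPrior) -> float:
    """Log marginal likelihood of counts under the merged hypothesis.

    The multinomial–Dirichlet marginal

        p(D | H1) = prod_j  Gamma(sum_l beta_jl) / Gamma(sum_l beta_jl + n_jl)
                    * prod_l Gamma(beta_jl + n_jl) / Gamma(beta_jl)

    evaluated in log space, additively over loci.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape != prior.beta.shape:
        raise ValueError(
            f"counts shape {counts.shape} does not match prior {prior.beta.shape}"
        )
    per_col = gammaln(prior.beta + counts) - prior._gl_beta
    locus_counts = np.add.reduceat(counts, prior.offsets[:-1])
    per_locus = prior._gl_beta_locus_sum - gammaln(
        prior._beta_locus_sum + locus_counts
    )
    return float(per_col.sum() + per_locus.sum())


def log_dpm_partition_prior(cluster_sizes, alpha: float, n: int | None = None) -> float:
    """Log prior probability of a partition under the Dirichlet process.

    For a partition of n items into K clusters of sizes n_1..n_K,

        f = alpha^K * prod_i (n_i - 1)! / prod_{i=1}^{n} (alpha + i - 1),

    the Ewens/CRP partition probability; summing exp over all set
    partitions of {1..n} gives 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    sizes = np.asarray(cluster_sizes, dtype=np.int64)
    if sizes.size < 1 or np.any(sizes < 1):
        raise ValueError("cluster sizes must be positive integers")
    total = int(sizes.sum())
    if n is not None and n != total:
        raise ValueError(f"cluster sizes sum to {total}, expected n={n}")
    k = sizes.size
    return float(
        k * math.log(alpha)
        + gammaln(sizes).sum()
        - np.log(alpha + np.arange(total)).sum()
    )


@dataclass
class NodeStats:
    """Statistics carried by one node of the Bayesian merge hierarchy.

    ``log_p_h1`` is the merged-hypothesis marginal likelihood of the
    node's pooled counts; ``log_p_tree`` the tree-marginal mixture;
    ``log_d`` the pi-recursion accumulator; ``log_pi`` the log prior
    probability of the merged hypothesis at this node.
    """

    members: np.ndarray
    counts: np.ndarray
    log_p_h1: float
    log_p_tree: float
    log_d: float
    log_pi: float
    log_1mpi: float  # log(1 - pi), kept exactly as log(d_i d_j / d_k)
    children: tuple["NodeStats", "NodeStats"] | None = None

    @property
    def size(self) -> int:
        return int(self.members.size)

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def log_r(self) -> float:
        return log_posterior_merge(self)


def make_leaf(members, counts: np.ndarray, prior: DirichletPrior,
              alpha: float = DEFAULT_ALPHA) -> NodeStats:
    """Leaf node for an initial cluster (possibly multi-member).

    The merge prior inside an initial cluster is fixed at pi = 1, so
    p(D|T) = p(D|H1) at the leaf; the d-accumulator starts at alpha
    regardless of member count (leaves are atomic and never split).
    """
    members = np.atleast_1d(np.asarray(members, dtype=np.intp))
    if members.size == 0:
        raise ValueError("a leaf needs at least one member")
    lp = log_marginal_h1(counts, prior)
    return NodeStats(
        members=np.sort(members),
        counts=np.asarray(counts, dtype=np.float64),
        log_p_h1=lp,
        log_p_tree=lp,
        log_d=math.log(alpha),
        log_pi=0.0,
        log_1mpi=-math.inf,
    )


def combine_nodes(left: NodeStats, right: NodeStats, prior: DirichletPrior,
                  alpha: float = DEFAULT_ALPHA) -> NodeStats:
    """Merge two disjoint subtrees into a new internal node.

    Implements the bottom-up recursions

        d_k  = alpha * Gamma(n_k) + d_i * d_j
        pi_k = alpha * Gamma(n_k) / d_k
        p(D_k|T_k) = pi_k p(D_k|H1) + (1 - pi_k) p(D_i|T_i) p(D_j|T_j)

    with cached count vectors summed, never recomputed from samples.
    """
    if np.intersect1d(left.members, right.members).size:
        raise ValueError("cannot merge overlapping member sets")
    n_k = left.size + right.size
    log_alpha_gamma = math.log(alpha) + gammaln(n_k)
    log_d = float(np.logaddexp(log_alpha_gamma, left.log_d + right.log_d))
    # both tail probabilities taken directly from the d-recursion so that
    # neither underflows when the factorial term dominates (pi -> 1)
    log_pi = min(0.0, log_alpha_gamma - log_d)
    log_1mpi = min(0.0, left.log_d + right.log_d - log_d)
    counts = left.counts + right.counts
    log_p_h1 = log_marginal_h1(counts, prior)
    log_p_tree = np.logaddexp(
        log_pi + log_p_h1,
        log_1mpi + left.log_p_tree + right.log_p_tree,
    )
    return NodeStats(
        members=np.sort(np.concatenate([left.members, right.members])),
        counts=counts,
        log_p_h1=log_p_h1,
        log_p_tree=float(log_p_tree),
        log_d=log_d,
        log_pi=float(log_pi),
        log_1mpi=float(log_1mpi),
        children=(left, right),
    )


def log_posterior_merge(node: NodeStats) -> float:
    """Log posterior probability r_k of the merged hypothesis, by Bayes.

    log r = log pi + log p(D|H1) - log p(D|T); always <= 0 since the
    denominator p(D|T) contains the numerator as one mixture term.
    """
    if node.children is None:
        raise ValueError("r is undefined for a leaf (no merge happened)")
    return min(0.0, node.log_pi + node.log_p_h1 - node.log_p_tree)
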