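"""Hyperparameter-scale selection by empirical Bayes on the Ward tree.

The marginal likelihood of the root node of a Bayesian merge hierarchy
approximates the probability of the whole dataset under a given prior.
A cheap singleton-leaf pass over the Ward hierarchy therefore scores a
candidate Dirichlet scale in one linear sweep, and a golden-section
search over the log10 of a single scalar multiplying every beta picks
the scale with the highest root evidence.  The expensive Bayesian
agglomeration then runs once, with the selected prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import SnpCountMatrix
from .model import (
    DEFAULT_ALPHA,
    DirichletPrior,
    NodeStats,
    combine_nodes,
    make_leaf,
    make_prior,
)

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0

#: Golden-section search bounds and tolerance, in log10(scale) units.
DEFAULT_SCALE_BOUNDS = (1e-2, 1e2)
DEFAULT_SCALE_TOL = 1e-3


@dataclass
class OptimizationResult:
    best_scale: float
    objective: float
    trace: list[tuple[float, float]]  # (scale, root log-evidence) pairs
    prior: DirichletPrior


def _singleton_counts(m: SnpCountMatrix) -> list[np.ndarray]:
    return [m.cluster_counts([i]) for i in range(m.n_samples)]


def tree_root_stats(
    hierarchy: np.ndarray,
    leaf_counts: list[np.ndarray],
    prior: DirichletPrior,
    alpha: float = DEFAULT_ALPHA,
) -> NodeStats:
    """Single bottom-up pass over a linkage matrix; returns the root node."""
    n = hierarchy.shape[0] + 1
    if len(leaf_counts) != n:
        raise ValueError("hierarchy size does not match number of leaves")
    nodes: list[NodeStats | None] = [
        make_leaf([i], leaf_counts[i], prior, alpha) for i in range(n)
    ]
    for row in hierarchy:
        i, j = int(row[0]), int(row[1])
        nodes.append(combine_nodes(nodes[i], nodes[j], prior, alpha))
        nodes[i] = nodes[j] = None  # free
    return nodes[-1]


def root_log_evidence(
    hierarchy: np.ndarray,
    m: SnpCountMatrix,
    prior: DirichletPrior,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Log p(D|T) at the root of a singleton-leaf Ward hierarchy."""
    if hierarchy.shape[0] + 1 != m.n_samples:
        raise ValueError("hierarchy does not span the alignment samples")
    return tree_root_stats(hierarchy, _singleton_counts(m), prior, alpha).log_p_tree


def optimize_prior_scale(
    hierarchy: np.ndarray,
    m: SnpCountMatrix,
    kind: str,
    alpha: float = DEFAULT_ALPHA,
    bounds: tuple[float, float] = DEFAULT_SCALE_BOUNDS,
    tol: float = DEFAULT_SCALE_TOL,
) -> OptimizationResult:
    """Golden-section search for the Dirichlet scale maximizing root evidence.

    The search runs over log10(scale) on [log10(lo), log10(hi)] to the
    given tolerance in log10 units.  The returned prior is the chosen
    kind with its pre-scale hyperparameters multiplied by the best
    scale; it is never worse (on this hierarchy) than scale = 1.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError(f"invalid scale bounds {bounds}")
    counts = _singleton_counts(m)
    trace: list[tuple[float, float]] = []

    def objective(x: float) -> float:
        scale = 10.0**x
        value = tree_root_stats(
            hierarchy, counts, make_prior(m, kind, scale), alpha
        ).log_p_tree
        if not math.isfinite(value):
            raise FloatingPointError(
                f"non-finite root evidence at prior scale {scale:g}"
            )
        trace.append((scale, value))
        return value

    a, b = math.log10(lo), math.log10(hi)
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = objective(c), objective(d)
    while (b - a) > tol:
        if fc >= fd:  # maximum is in [a, d]
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = objective(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = objective(d)

    # guarantee the optimized prior is no worse than the unit scale
    if lo <= 1.0 <= hi:
        objective(0.0)
    best_scale, best_value = max(trace, key=lambda sv: sv[1])
    return OptimizationResult(
        best_scale=best_scale,
        objective=best_value,
        trace=trace,
        prior=make_prior(m, kind, best_scale),
    )
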