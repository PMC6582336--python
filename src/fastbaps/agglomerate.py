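"""Greedy Bayesian agglomeration of initial clusters and the r-cut.

Starting from the K_init initial-cluster leaves, every round computes
the posterior merge probability r for all top-level pairs and merges
the pair with the highest r; after a merge only the new node's pairs
are evaluated, so the whole agglomeration costs O(loci * K_init^2).
The final partition keeps every subtree whose merge was justified
(r >= 0.5 by default) and splits the rest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, SnpCountMatrix, build_snp_matrix
from .initial import InitialClustering, initial_clustering
from .model import (
    DEFAULT_ALPHA,
    DirichletPrior,
    NodeStats,
    combine_nodes,
    make_leaf,
    make_prior,
)
from .optimize import (
    DEFAULT_SCALE_BOUNDS,
    DEFAULT_SCALE_TOL,
    OptimizationResult,
    optimize_prior_scale,
)

#: Posterior merge probability below which a merge is rejected at the cut.
DEFAULT_CUT_THRESHOLD = 0.5

#: Prior options accepted by the pipeline; "optimized-*" add the
#: golden-section scale search on the Ward hierarchy.
PIPELINE_PRIORS = (
    "baps",
    "symmetric",
    "bhc",
    "optimized-baps",
    "optimized-symmetric",
)


@dataclass
class Partition:
    """Assignment of sample labels to clusters.

    Cluster indices are 1-based and ordered by decreasing cluster size
    (ties by smallest member index), so cluster 1 is always the largest.
    """

    labels: list[str]
    assignment: np.ndarray  # 1-based cluster index per label

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.intp)
        if len(self.labels) != self.assignment.size:
            raise ValueError("labels and assignment lengths differ")
        present = np.unique(self.assignment)
        if present[0] < 1 or present[-1] != present.size:
            raise ValueError("cluster indices must be contiguous and 1-based")

    @property
    def k(self) -> int:
        return int(self.assignment.max())

    def clusters(self) -> list[list[str]]:
        return [
            [l for l, a in zip(self.labels, self.assignment) if a == g]
            for g in range(1, self.k + 1)
        ]

    @classmethod
    def from_member_sets(cls, labels: list[str], member_sets) -> "Partition":
        """Build from member index arrays, applying the canonical order."""
        ordered = sorted(
            (np.sort(np.asarray(ms, dtype=np.intp)) for ms in member_sets),
            key=lambda ms: (-ms.size, ms[0]),
        )
        assignment = np.zeros(len(labels), dtype=np.intp)
        for g, ms in enumerate(ordered, start=1):
            assignment[ms] = g
        if np.any(assignment == 0):
            raise ValueError("member sets do not cover all samples")
        return cls(labels=labels, assignment=assignment)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sequence_id\tcluster\n")
            for label, a in zip(self.labels, self.assignment):
                fh.write(f"{label}\t{a}\n")

    @classmethod
    def read_tsv(cls, path) -> "Partition":
        labels, raw = [], []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("sequence_id"):
                raise ValueError(f"{path}: expected a sequence_id\\tcluster header")
            for line in fh:
                if line.strip():
                    label, a = line.rstrip("\n").split("\t")
                    labels.append(label)
                    raw.append(a)
        groups: dict[str, list[int]] = {}
        for i, a in enumerate(raw):
            groups.setdefault(a, []).append(i)
        return cls.from_member_sets(labels, list(groups.values()))


@dataclass
class ClusterTree:
    """Binary Bayesian merge hierarchy over the initial clusters."""

    root: NodeStats
    leaves: list[NodeStats]
    merge_order: list[tuple[int, int, float]] = field(default_factory=list)

    def internal_nodes(self) -> list[NodeStats]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.children is not None:
                out.append(node)
                stack.extend(node.children)
        return out

    def to_newick(self, labels: list[str]) -> str:
        """Newick export; multi-member leaves become ladderized clades."""

        def fmt(node: NodeStats) -> str:
            if node.children is not None:
                return f"({fmt(node.children[0])},{fmt(node.children[1])})"
            names = [labels[i] for i in node.members]
            out = names[0]
            for name in names[1:]:
                out = f"({out},{name})"
            return out

        return fmt(self.root) + ";"

    def to_json(self, labels: list[str]) -> str:
        """JSON dump with per-node log_r, log_p_h1 and members."""

        def node_dict(node: NodeStats) -> dict:
            d = {
                "members": [labels[i] for i in node.members],
                "log_p_h1": node.log_p_h1,
                "log_p_tree": node.log_p_tree,
            }
            if node.children is not None:
                d["log_r"] = node.log_r
                d["children"] = [node_dict(c) for c in node.children]
            return d

        return json.dumps(node_dict(self.root), indent=1)


def run_bhc(
    leaves: list[NodeStats],
    prior: DirichletPrior,
    alpha: float = DEFAULT_ALPHA,
) -> ClusterTree:
    """Greedy Bayesian hierarchical clustering over initial-cluster leaves.

    Repeatedly merges the pair of top-level subtrees with the highest
    posterior merge probability r until a single tree remains.  Ties on
    log r are broken towards the lexicographically smallest pair of
    original leaf indices.
    """
    if not leaves:
        raise ValueError("need at least one leaf")
    if len(leaves) == 1:
        return ClusterTree(root=leaves[0], leaves=list(leaves))

    active: dict[int, NodeStats] = dict(enumerate(leaves))
    min_leaf = {i: i for i in active}  # smallest original leaf index under node
    next_id = len(leaves)
    cache: dict[tuple[int, int], float] = {}

    def pair_log_r(i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        if key not in cache:
            merged = combine_nodes(active[key[0]], active[key[1]], prior, alpha)
            cache[key] = merged.log_r
        return cache[key]

    ids = sorted(active)
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            pair_log_r(ids[a_i], ids[b_i])

    merge_order: list[tuple[int, int, float]] = []
    while len(active) > 1:
        best_key, best_r, best_tie = None, -math.inf, (math.inf, math.inf)
        for (i, j), log_r in cache.items():
            tie = tuple(sorted((min_leaf[i], min_leaf[j])))
            if log_r > best_r or (log_r == best_r and tie < best_tie):
                best_key, best_r, best_tie = (i, j), log_r, tie
        i, j = best_key
        merged = combine_nodes(active[i], active[j], prior, alpha)
        merge_order.append((i, j, merged.log_r))
        for key in [k for k in cache if i in k or j in k]:
            del cache[key]
        del active[i], active[j]
        new_id = next_id
        next_id += 1
        active[new_id] = merged
        min_leaf[new_id] = min(min_leaf[i], min_leaf[j])
        for other in active:
            if other != new_id:
                pair_log_r(other, new_id)

    root = next(iter(active.values()))
    return ClusterTree(root=root, leaves=list(leaves), merge_order=merge_order)


def cut_tree(
    tree: ClusterTree, threshold: float = DEFAULT_CUT_THRESHOLD,
    labels: list[str] | None = None,
) -> Partition:
    """Cut the merge hierarchy where the posterior merge probability drops.

    Top-down from the root: a node whose merge was accepted
    (r >= threshold), or a leaf, becomes one output cluster; otherwise
    both children are visited.  Initial-cluster leaves are atomic.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    log_thr = math.log(threshold)
    member_sets: list[np.ndarray] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node.children is None or node.log_r >= log_thr:
            member_sets.append(node.members)
        else:
            stack.extend(node.children)
    n = tree.root.size
    if labels is None:
        labels = [str(i) for i in range(n)]
    return Partition.from_member_sets(labels, member_sets)


def build_leaves(
    m: SnpCountMatrix,
    init: InitialClustering,
    prior: DirichletPrior,
    alpha: float = DEFAULT_ALPHA,
) -> list[NodeStats]:
    """Initial-cluster leaves with pooled counts and the pi0 = 1 convention."""
    return [
        make_leaf(members, m.cluster_counts(members), prior, alpha)
        for members in init.groups()
    ]


@dataclass
class FastbapsResult:
    partition: Partition
    tree: ClusterTree
    matrix: SnpCountMatrix
    init: InitialClustering
    prior: DirichletPrior
    optimization: OptimizationResult | None = None


def fastbaps(
    aln: Alignment,
    *,
    prior: str = "optimized-baps",
    k_init: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    threshold: float = DEFAULT_CUT_THRESHOLD,
    pca_threshold: int = 10_000,
    n_components: int = 50,
    force_pca: bool = False,
    pca_seed: int = 42,
    opt_bounds: tuple[float, float] = DEFAULT_SCALE_BOUNDS,
    opt_tol: float = DEFAULT_SCALE_TOL,
) -> FastbapsResult:
    """The full clustering pipeline on an alignment.

    Variable sites are extracted, a Ward hierarchy seeds K_init initial
    clusters, the Dirichlet prior scale is optionally tuned by maximum
    root evidence on that hierarchy, and greedy Bayesian agglomeration
    plus the r-cut produce the final partition.  Deterministic given
    the configuration.
    """
    if prior not in PIPELINE_PRIORS:
        raise ValueError(
            f"unknown prior {prior!r}; expected one of {PIPELINE_PRIORS}"
        )
    m = build_snp_matrix(aln)
    init = initial_clustering(
        m,
        k_init,
        pca_threshold=pca_threshold,
        n_components=n_components,
        force_pca=force_pca,
        pca_seed=pca_seed,
    )
    kind = {"bhc": "bhc_counts"}.get(prior.replace("optimized-", ""), None)
    if kind is None:
        kind = prior.replace("optimized-", "")
    opt = None
    if prior.startswith("optimized-"):
        opt = optimize_prior_scale(
            init.hierarchy, m, kind, alpha, bounds=opt_bounds, tol=opt_tol
        )
        dirichlet = opt.prior
    else:
        dirichlet = make_prior(m, kind, scale=1.0)
    leaves = build_leaves(m, init, dirichlet, alpha)
    tree = run_bhc(leaves, dirichlet, alpha)
    partition = cut_tree(tree, threshold, labels=aln.labels)
    return FastbapsResult(
        partition=partition,
        tree=tree,
        matrix=m,
        init=init,
        prior=dirichlet,
        optimization=opt,
    )
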