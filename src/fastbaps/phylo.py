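"""Partitioning a pre-computed rooted hierarchy with the DPM model.

Instead of building its own merge hierarchy, the model can condition
on a user-supplied rooted tree (e.g. a phylogeny): one bottom-up pass
computes the Bayesian merge statistics at every node, and the same
posterior-probability cut used on the agglomerative tree then selects
the clades that form the partition.  Each node's count vector is the
sum of its children's, so the whole pass is linear in the number of
nodes.  Branch lengths are parsed but ignored — the model sees only
topology and alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .agglomerate import DEFAULT_CUT_THRESHOLD, ClusterTree, Partition, cut_tree
from .alignment import SnpCountMatrix
from .model import (
    DEFAULT_ALPHA,
    DirichletPrior,
    NodeStats,
    combine_nodes,
    make_leaf,
)


class TreeError(ValueError):
    """Raised for unusable tree input."""


@dataclass
class PartitionAudit:
    """Bookkeeping returned alongside a tree partition."""

    n_nodes: int
    n_edges: int
    count_additions: int = 0


def read_newick(path, *, midpoint_root: bool = False) -> dendropy.Tree:
    """Read a rooted tree from a Newick file.

    A tree whose root has more than two children is treated as
    unrooted; it is rejected unless ``midpoint_root`` asks for midpoint
    rooting.  Leaf labels must be unique; underscores are preserved.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise TreeError(f"duplicate leaf labels in {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate leaf labels: {dupes}")
    root_children = tree.seed_node.child_nodes()
    if len(root_children) > 2:
        if not midpoint_root:
            raise TreeError(
                "tree root has more than two children (unrooted tree?); "
                "re-root it or pass midpoint_root=True / --midpoint-root"
            )
        for edge in tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 1.0  # midpoint needs lengths; topology-only tree
        tree.reroot_at_midpoint(update_bipartitions=True)
    return tree


def _check_labels(tree: dendropy.Tree, labels: list[str]) -> dict[str, int]:
    tree_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    aln_labels = set(labels)
    missing = sorted(aln_labels - tree_labels)
    extra = sorted(tree_labels - aln_labels)
    if missing or extra:
        raise TreeError(
            f"tree/alignment label mismatch; missing from tree: {missing}; "
            f"absent from alignment: {extra}"
        )
    return {label: i for i, label in enumerate(labels)}


def partition_tree(
    tree: dendropy.Tree,
    m: SnpCountMatrix,
    prior: DirichletPrior,
    alpha: float = DEFAULT_ALPHA,
    threshold: float = DEFAULT_CUT_THRESHOLD,
    *,
    labels: list[str] | None = None,
    return_audit: bool = False,
):
    """Partition a rooted tree into clades justified by the DPM model.

    Leaves are singleton nodes (pi = 1, d = alpha); every internal node
    combines its children bottom-up (multifurcations are binarized as a
    left-to-right ladder first), and the top-down cut accepts a clade
    whenever its merge posterior r >= threshold, recursing into the
    children of the node's original (pre-binarization) structure
    otherwise.  Every output cluster is a clade of the input tree.
    """
    if labels is None:
        labels = m.labels
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    index_of = _check_labels(tree, labels)
    audit = PartitionAudit(
        n_nodes=sum(1 for _ in tree.preorder_node_iter()),
        n_edges=sum(1 for _ in tree.preorder_node_iter()) - 1,
    )

    stats: dict[int, NodeStats] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index_of[node.taxon.label]
            stats[id(node)] = make_leaf([i], m.cluster_counts([i]), prior, alpha)
        else:
            children = node.child_nodes()
            acc = stats[id(children[0])]
            for child in children[1:]:  # ladderized binarization
                acc = combine_nodes(acc, stats[id(child)], prior, alpha)
                audit.count_additions += 1
            stats[id(node)] = acc

    log_thr = math.log(threshold)
    member_sets: list[np.ndarray] = []
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        st = stats[id(node)]
        if st.children is None or st.log_r >= log_thr:
            member_sets.append(st.members)
        else:
            stack.extend(node.child_nodes())
    partition = Partition.from_member_sets(labels, member_sets)
    if return_audit:
        return partition, audit
    return partition


def cluster_tree_to_dendropy(tree: ClusterTree, labels: list[str]) -> dendropy.Tree:
    """Round-trip a Bayesian merge tree through its Newick string."""
    out = dendropy.Tree.get(
        data=tree.to_newick(labels), schema="newick", preserve_underscores=True
    )
    out.is_rooted = True
    return out
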