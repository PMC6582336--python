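"""Scoring clusterings: Fowlkes–Mallows and phylogeny pair-consistency.

The Fowlkes–Mallows index is the geometric mean of pairwise precision
and recall between two partitions,

    FM = sqrt( TP/(TP+FP) * TP/(TP+FN) ),

where TP counts pairs co-clustered in both partitions, FP pairs
co-clustered only in the inferred partition, FN pairs co-clustered
only in the reference.  Degenerate cases (the formula is 0/0): two
all-singleton partitions agree perfectly and score 1; TP = 0 with any
disagreeing pairs scores 0.

The phylogeny consistency error judges a clustering against a tree
with no ground truth: a within-cluster pair is a "false positive" if
the clade of its most recent common ancestor contains a leaf from
another cluster, and the error is the fraction of within-cluster pairs
that are false positives.
"""

from __future__ import annotations

import math
import warnings

import dendropy
import numpy as np

from .agglomerate import Partition


def fowlkes_mallows(truth: Partition, inferred: Partition) -> float:
    """Fowlkes–Mallows index between two partitions of the same labels."""
    if truth.labels != inferred.labels:
        if set(truth.labels) != set(inferred.labels):
            raise ValueError("partitions are over different label sets")
        order = {l: i for i, l in enumerate(truth.labels)}
        perm = np.argsort([order[l] for l in inferred.labels])
        b = inferred.assignment[perm]
    else:
        b = inferred.assignment
    a = truth.assignment
    contingency = np.zeros((truth.k, int(b.max())), dtype=np.int64)
    np.add.at(contingency, (a - 1, b - 1), 1)

    def pairs(counts: np.ndarray) -> float:
        return float((counts * (counts - 1)).sum() / 2)

    tp = pairs(contingency)
    pairs_truth = pairs(contingency.sum(axis=1))  # TP + FN
    pairs_inferred = pairs(contingency.sum(axis=0))  # TP + FP
    if pairs_truth == 0 and pairs_inferred == 0:
        return 1.0  # both all-singletons: identical partitions
    if tp == 0:
        return 0.0
    return math.sqrt(tp / pairs_inferred * tp / pairs_truth)


def phylo_consistency_error(partition: Partition, tree: dendropy.Tree) -> float:
    """Proportion of within-cluster pairs inconsistent with a tree.

    A pair (u, v) from one cluster is inconsistent if the clade of
    MRCA(u, v) contains any leaf assigned to a different cluster.  All
    pairs whose MRCA is a given node are counted at once: they are the
    cross-child pairs of cluster members under that node.
    """
    leaf_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if set(leaf_labels) != set(partition.labels):
        raise ValueError("tree leaves do not match partition labels")
    cluster_of = dict(zip(partition.labels, partition.assignment))

    post = list(tree.postorder_node_iter())
    k = partition.k
    # per node: total leaves below, and per-cluster member counts below
    size = {id(n): 0 for n in post}
    ccount = {id(n): np.zeros(k, dtype=np.int64) for n in post}
    for node in post:
        if node.is_leaf():
            size[id(node)] = 1
            ccount[id(node)][cluster_of[node.taxon.label] - 1] = 1
        else:
            for child in node.child_nodes():
                size[id(node)] += size[id(child)]
                ccount[id(node)] += ccount[id(child)]

    total_pairs = 0.0
    fp_pairs = 0.0
    for node in post:
        if node.is_leaf():
            continue
        cc = ccount[id(node)]
        sq = cc.astype(np.float64) ** 2
        for child in node.child_nodes():
            sq -= ccount[id(child)].astype(np.float64) ** 2
        mrca_pairs = sq / 2.0  # per-cluster pairs whose MRCA is this node
        total_pairs += mrca_pairs.sum()
        impure = cc < size[id(node)]  # clade holds leaves outside the cluster
        fp_pairs += mrca_pairs[impure].sum()

    if total_pairs == 0:
        warnings.warn(
            "partition has only singleton clusters; consistency error is 0",
            stacklevel=2,
        )
        return 0.0
    return fp_pairs / total_pairs
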