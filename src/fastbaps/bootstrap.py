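"""Cluster stability by bootstrapping the variable loci.

Each replicate resamples the retained variable loci with replacement,
reruns the full clustering pipeline (including prior-scale
optimization if configured) and records, for every pair of samples,
whether they land in the same cluster.  The summed binary
co-clustering matrices are invariant to cluster label switching and
their dimension does not depend on the number of clusters a replicate
finds, so the accumulated matrix directly measures how stably two
samples travel together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agglomerate import fastbaps
from .alignment import Alignment, AlignmentError, build_snp_matrix

DEFAULT_N_REPLICATES = 100
_MAX_REDRAWS = 10


@dataclass
class StabilityMatrix:
    """Symmetric co-clustering counts accumulated over replicates."""

    labels: list[str]
    counts: np.ndarray
    n_replicates: int

    def support(self, i: int, j: int) -> float:
        """Fraction of replicates co-clustering samples i and j."""
        return self.counts[i, j] / self.n_replicates

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for label, row in zip(self.labels, self.counts):
                fh.write(label + "\t" + "\t".join(str(int(c)) for c in row) + "\n")

    def plot_heatmap(self, path, *, hierarchy=None) -> None:
        """Optional heatmap, ordered by a full-run hierarchy if given."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from scipy.cluster import hierarchy as sch

        order = np.arange(len(self.labels))
        if hierarchy is not None:
            order = np.asarray(sch.leaves_list(hierarchy))
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(
            self.counts[np.ix_(order, order)] / self.n_replicates,
            cmap="viridis",
            vmin=0,
            vmax=1,
        )
        fig.colorbar(im, ax=ax, label="co-clustering support")
        ax.set_xticks([])
        ax.set_yticks([])
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _coassignment(assignment: np.ndarray) -> np.ndarray:
    return (assignment[:, None] == assignment[None, :]).astype(np.int64)


def bootstrap_clusters(
    aln: Alignment,
    n_replicates: int = DEFAULT_N_REPLICATES,
    seed: int = 0,
    **fastbaps_kwargs,
) -> StabilityMatrix:
    """Accumulate co-clustering counts over loci-bootstrap replicates.

    Keyword arguments are forwarded to :func:`fastbaps` unchanged, so
    the replicates run exactly the configured pipeline.  Reproducible
    given the seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    m = build_snp_matrix(aln)
    seq_matrix = aln.to_matrix()[:, m.loci]
    n_loci = m.n_loci

    counts = np.zeros((aln.n, aln.n), dtype=np.int64)
    for _ in range(n_replicates):
        for attempt in range(_MAX_REDRAWS):
            cols = rng.integers(0, n_loci, size=n_loci)
            resampled = Alignment(
                labels=list(aln.labels),
                sequences=[
                    row.tobytes().decode() for row in seq_matrix[:, cols]
                ],
            )
            try:
                result = fastbaps(resampled, **fastbaps_kwargs)
                break
            except AlignmentError:
                continue  # a degenerate draw; redraw the loci
        else:
            raise AlignmentError(
                f"no usable bootstrap replicate after {_MAX_REDRAWS} draws"
            )
        counts += _coassignment(result.partition.assignment)
    return StabilityMatrix(
        labels=list(aln.labels), counts=counts, n_replicates=n_replicates
    )
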