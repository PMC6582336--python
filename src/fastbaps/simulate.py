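"""Synthetic structured populations with known deme labels.

The generator emulates K discrete demes under the no-admixture model
that the clustering assumes: every locus is biallelic, each deme has
its own allele frequency drawn around a global frequency, and each
sample draws its alleles independently per locus.  A ``mixing``
parameter in [0, 1] blends the deme-specific frequencies toward the
global mean — 0 gives maximally differentiated demes, 1 erases all
between-deme signal — playing the role migration plays in a coalescent
simulation without modelling genealogies or linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agglomerate import Partition
from .alignment import BASES, Alignment

#: Dirichlet concentration for allele-frequency draws: Jeffreys prior
#: for a biallelic locus, giving the U-shaped frequency spectra typical
#: of SNP panels.
DEFAULT_DIRICHLET_CONC = 0.5


@dataclass
class SyntheticConfig:
    """Parameters of the Dirichlet-deme generator."""

    k_demes: int
    n_per_deme: int | list[int]
    n_loci: int
    dirichlet_conc: float = DEFAULT_DIRICHLET_CONC
    mixing: float = 0.0
    n_alleles: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_demes < 1:
            raise ValueError("k_demes must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must lie in [0, 1]")
        if self.dirichlet_conc <= 0:
            raise ValueError("dirichlet_conc must be positive")
        if not 2 <= self.n_alleles <= 4:
            raise ValueError("n_alleles must be in {2, 3, 4}")

    @property
    def deme_sizes(self) -> list[int]:
        if isinstance(self.n_per_deme, int):
            return [self.n_per_deme] * self.k_demes
        if len(self.n_per_deme) != self.k_demes:
            raise ValueError("n_per_deme list must have k_demes entries")
        return list(self.n_per_deme)


@dataclass
class LabelledDataset:
    alignment: Alignment
    truth: Partition


def simulate(cfg: SyntheticConfig) -> LabelledDataset:
    """Draw a labelled dataset from the Dirichlet-deme model.

    Per locus: the allele set is a random subset of ACGT of size
    ``n_alleles`` with a global frequency vector drawn from
    Dirichlet(conc * 1); each deme independently draws a frequency
    vector from the same Dirichlet and the two are blended as
    ``(1 - mixing) * deme + mixing * global``.  Genotypes are i.i.d.
    categorical per sample per locus.  Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.deme_sizes
    n = sum(sizes)
    gamma = np.full(cfg.n_alleles, cfg.dirichlet_conc)

    allele_sets = np.stack(
        [rng.choice(4, size=cfg.n_alleles, replace=False) for _ in range(cfg.n_loci)]
    )
    global_freq = rng.dirichlet(gamma, size=cfg.n_loci)  # (loci, alleles)
    deme_freq = np.empty((cfg.k_demes, cfg.n_loci, cfg.n_alleles))
    for d in range(cfg.k_demes):
        raw = rng.dirichlet(gamma, size=cfg.n_loci)
        deme_freq[d] = (1.0 - cfg.mixing) * raw + cfg.mixing * global_freq

    sequences: list[str] = []
    labels: list[str] = []
    assignment: list[int] = []
    for d, size in enumerate(sizes):
        cdf = np.cumsum(deme_freq[d], axis=1)  # (loci, alleles)
        for s in range(size):
            u = rng.random(cfg.n_loci)
            idx = (u[:, None] > cdf).sum(axis=1)  # allele index per locus
            bases = allele_sets[np.arange(cfg.n_loci), idx]
            sequences.append("".join(BASES[b] for b in bases))
            labels.append(f"d{d + 1}-{s + 1}")
            assignment.append(d)

    aln = Alignment(labels=labels, sequences=sequences)
    truth = Partition.from_member_sets(
        labels,
        [np.nonzero(np.asarray(assignment) == d)[0] for d in range(cfg.k_demes)],
    )
    return LabelledDataset(alignment=aln, truth=truth)
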