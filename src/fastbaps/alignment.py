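"""Alignment input and the sparse allele-count representation.

The model downstream only ever sees integer allele counts at variable
(SNP) sites, so the alignment is reduced to a sparse per-sample,
per-locus, per-allele count structure.  Gaps, ``N`` and IUPAC ambiguity
codes contribute no count at all: a sample is simply "missing" at that
locus.  At each retained locus the majority allele is the implicit zero
of the sparse encoding, so memory scales with the number of
non-majority (i.e. minor-allele or missing) entries rather than with
the full one-hot matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from scipy import sparse

BASES = "ACGT"
_BASE_CODES = np.frombuffer(BASES.encode(), dtype=np.uint8)


class AlignmentError(ValueError):
    """Raised for malformed or unusable alignment input."""


@dataclass
class Alignment:
    """A multiple sequence alignment of equal-length nucleotide strings.

    Parameters
    ----------
    labels
        Unique sequence identifiers, in file order.
    sequences
        Upper-case nucleotide strings, all the same length.
    """

    labels: list[str]
    sequences: list[str]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise AlignmentError("an alignment needs at least 2 sequences")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise AlignmentError(f"duplicate sequence labels: {dupes}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(
                f"sequences have unequal lengths: {sorted(lengths)}"
            )
        self.length = lengths.pop()
        if self.length == 0:
            raise AlignmentError("sequences are empty")
        self.sequences = [s.upper().replace("U", "T") for s in self.sequences]

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_matrix(self) -> np.ndarray:
        """Return the alignment as an (n, length) uint8 byte matrix."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype=np.uint8
        ).reshape(self.n, self.length)


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file.

    Sequences are upper-cased and ``U`` is mapped to ``T``.  Records of
    unequal length, duplicate identifiers or fewer than two records are
    rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentError(f"{path}: need at least 2 FASTA records")
    return Alignment(
        labels=[r.id for r in records],
        sequences=[str(r.seq) for r in records],
    )


@dataclass
class SnpCountMatrix:
    """Sparse per-sample, per-locus allele counts at variable sites.

    Attributes
    ----------
    labels
        Sample labels in alignment order.
    loci
        0-based column indices of retained variable sites in the
        original alignment.
    alleles_per_locus
        For each retained locus, the observed alleles in alphabetical
        order (subset of ``ACGT``), at least two per locus.
    offsets
        Flat column offsets: the (locus j, allele a) count lives at flat
        index ``offsets[j] + a``; ``offsets[-1]`` is the total number of
        (locus, allele) columns.
    nonmajor
        CSR matrix (n_samples x total columns) with a 1 where sample i
        carries a non-majority allele; majority-allele carriage is
        implicit.
    missing
        CSR matrix (n_samples x n_loci) with a 1 where sample i has no
        countable base (gap, N, ambiguity code) at retained locus j.
    major_flat
        Flat column index of the majority allele at each locus (ties in
        majority broken by alphabetical allele order).
    """

    labels: list[str]
    loci: np.ndarray
    alleles_per_locus: list[str]
    offsets: np.ndarray
    nonmajor: sparse.csr_matrix
    missing: sparse.csr_matrix
    major_flat: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.nonmajor.shape[0]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_alleles(self) -> np.ndarray:
        """Number of observed alleles N_A(j) at each retained locus."""
        return np.diff(self.offsets)

    @property
    def n_columns(self) -> int:
        return int(self.offsets[-1])

    def cluster_counts(self, members) -> np.ndarray:
        """Allele counts n_jl summed over a set of samples.

        Returns a flat float array over (locus, allele) columns, aligned
        with ``offsets``.  Additive over disjoint member sets.
        """
        members = np.atleast_1d(np.asarray(members, dtype=np.intp))
        if members.size == 0:
            raise ValueError("empty member set")
        if members.min() < 0 or members.max() >= self.n_samples:
            raise IndexError("member index out of range")
        if len(np.unique(members)) != members.size:
            raise ValueError("duplicate member indices")
        counts = np.asarray(
            self.nonmajor[members].sum(axis=0), dtype=np.float64
        ).ravel()
        miss = np.asarray(self.missing[members].sum(axis=0)).ravel()
        per_locus_nonmajor = np.add.reduceat(counts, self.offsets[:-1])
        counts[self.major_flat] = members.size - miss - per_locus_nonmajor
        return counts

    def one_hot(self) -> sparse.csr_matrix:
        """Full one-hot allele matrix (majority columns made explicit)."""
        n = self.n_samples
        present = np.ones((n, self.n_loci)) - self.missing.toarray()
        # subtract non-majority carriage per locus to find majority carriers
        nm = np.asarray(self.nonmajor.toarray(), dtype=np.float64)
        per_locus_nm = np.add.reduceat(nm, self.offsets[:-1], axis=1)
        full = nm
        full[:, self.major_flat] = present - per_locus_nm
        return sparse.csr_matrix(full)

    def write_locus_counts_tsv(self, path) -> None:
        """Debug dump of total per-locus allele counts (1-based positions)."""
        total = self.cluster_counts(np.arange(self.n_samples))
        with open(path, "w") as fh:
            fh.write("position\tallele\tcount\n")
            for j, pos in enumerate(self.loci):
                for a, allele in enumerate(self.alleles_per_locus[j]):
                    fh.write(
                        f"{pos + 1}\t{allele}\t{int(total[self.offsets[j] + a])}\n"
                    )


def build_snp_matrix(aln: Alignment) -> SnpCountMatrix:
    """Extract variable sites and build the sparse allele-count matrix.

    A column is retained iff at least two distinct bases from
    ``{A,C,G,T}`` occur among its non-missing characters.  Everything
    else (gaps, ``N``, ambiguity codes) is treated as missing and
    carries zero counts.
    """
    arr = aln.to_matrix()
    n, L = arr.shape
    is_base = arr[:, :, None] == _BASE_CODES[None, None, :]  # (n, L, 4)
    base_counts = is_base.sum(axis=0)  # (L, 4)
    variable = (base_counts > 0).sum(axis=1) >= 2
    loci = np.nonzero(variable)[0]
    if loci.size == 0:
        raise AlignmentError("no variable sites in alignment")

    sub = is_base[:, loci, :]  # (n, n_loci, 4)
    sub_counts = base_counts[loci]  # (n_loci, 4)
    alleles_per_locus: list[str] = []
    offsets = [0]
    major_flat = []
    col_of = np.full((loci.size, 4), -1, dtype=np.intp)
    for j in range(loci.size):
        observed = np.nonzero(sub_counts[j] > 0)[0]
        alleles_per_locus.append("".join(BASES[b] for b in observed))
        col_of[j, observed] = offsets[-1] + np.arange(observed.size)
        # argmax on alphabetically ordered counts breaks majority ties A<C<G<T
        major = observed[np.argmax(sub_counts[j, observed])]
        major_flat.append(col_of[j, major])
        offsets.append(offsets[-1] + observed.size)
    offsets = np.asarray(offsets, dtype=np.intp)
    major_flat = np.asarray(major_flat, dtype=np.intp)

    # non-majority carriage and missingness, built densely then sparsified
    # (alignment-sized temporaries; fine for in-memory alignments)
    nonmajor = np.zeros((n, int(offsets[-1])), dtype=np.int32)
    for j in range(loci.size):
        for b in range(4):
            col = col_of[j, b]
            if col < 0 or col == major_flat[j]:
                continue
            nonmajor[:, col] = sub[:, j, b]
    missing = (sub.sum(axis=2) == 0).astype(np.int32)

    return SnpCountMatrix(
        labels=list(aln.labels),
        loci=loci,
        alleles_per_locus=alleles_per_locus,
        offsets=offsets,
        nonmajor=sparse.csr_matrix(nonmajor),
        missing=sparse.csr_matrix(missing),
        major_flat=major_flat,
    )


def write_fasta(aln: Alignment, path) -> None:
    """Write an alignment to FASTA (plain, one sequence per line)."""
    with open(path, "w") as fh:
        for label, seq in zip(aln.labels, aln.sequences):
            fh.write(f">{label}\n{seq}\n")
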