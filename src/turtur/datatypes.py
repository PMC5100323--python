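"""Core in-memory containers shared across the pipeline.

Two substrates carry all downstream statistics:

* :class:`SNPDataset` — a diploid genotype matrix over unlinked biallelic
  loci, entries counting copies of the derived/alternate allele (0, 1, 2)
  with ``-1`` marking missing calls.
* :class:`HaplotypeAlignment` — an aligned set of haploid sequences
  (mitochondrial cytochrome-b in the motivating study).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1

#: characters treated as unambiguous bases in alignments
VALID_BASES = frozenset(b"ACGT")
#: full accepted alphabet for alignment input
IUPAC_CHARS = frozenset(b"ACGTRYSWKMBDHVN-")


@dataclass
class SNPDataset:
    """Diploid genotypes at unlinked biallelic loci.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_loci)`` integer matrix of derived-allele doses in
        ``{0, 1, 2}``; missing genotypes are coded ``-1``.
    individual_ids, locus_ids
        Row / column labels.
    populations
        Optional per-individual population (sampling locality) labels.
    groups
        Optional per-individual group labels (e.g. migratory flyway).
    """

    genotypes: np.ndarray
    individual_ids: list[str] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)
    populations: list[str] | None = None
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if not np.isin(g, (MISSING, 0, 1, 2)).all():
            raise ValueError("genotype entries must be in {-1, 0, 1, 2}")
        self.genotypes = g.astype(np.int8, copy=False)
        if not self.individual_ids:
            self.individual_ids = [f"ind{i:04d}" for i in range(g.shape[0])]
        if not self.locus_ids:
            self.locus_ids = [f"locus{j:05d}" for j in range(g.shape[1])]
        if len(self.individual_ids) != g.shape[0]:
            raise ValueError("individual_ids length mismatch")
        if len(self.locus_ids) != g.shape[1]:
            raise ValueError("locus_ids length mismatch")
        for labels, what in ((self.populations, "populations"), (self.groups, "groups")):
            if labels is not None and len(labels) != g.shape[0]:
                raise ValueError(f"{what} length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus (derived copies, total non-missing copies)."""
        g = self.genotypes
        called = g >= 0
        derived = np.where(called, g, 0).sum(axis=0)
        total = 2 * called.sum(axis=0)
        return derived.astype(np.int64), total.astype(np.int64)

    def missing_fraction(self) -> float:
        return float((self.genotypes == MISSING).mean())

    def __eq__(self, other: object) -> bool:  # value semantics for round-trip tests
        if not isinstance(other, SNPDataset):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.individual_ids == other.individual_ids
            and self.locus_ids == other.locus_ids
            and self.populations == other.populations
            and self.groups == other.groups
        )


@dataclass
class HaplotypeAlignment:
    """Aligned haploid sequences of common length.

    Sequences are stored as an ``(n, L)`` byte matrix over the IUPAC
    alphabet (uppercase). Diversity statistics treat any column containing a
    character outside ``{A, C, G, T}`` according to the chosen deletion mode.
    """

    sequences: np.ndarray
    ids: list[str] = field(default_factory=list)
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        seqs = self.sequences
        if isinstance(seqs, (list, tuple)):
            if len({len(s) for s in seqs}) > 1:
                raise ValueError("sequences must have equal lengths")
            seqs = np.array([list(s.upper().encode()) for s in seqs], dtype=np.uint8)
        seqs = np.asarray(seqs, dtype=np.uint8)
        if seqs.ndim != 2:
            raise ValueError("alignment must be 2-D (n sequences x L sites)")
        bad = set(seqs.tobytes()) - {ord(c) for c in "ACGTRYSWKMBDHVN-"}
        if bad:
            raise ValueError(f"non-IUPAC characters in alignment: {sorted(chr(b) for b in bad)}")
        self.sequences = seqs
        if not self.ids:
            self.ids = [f"seq{i:04d}" for i in range(seqs.shape[0])]
        if len(self.ids) != seqs.shape[0]:
            raise ValueError("ids length mismatch")
        if self.populations is not None and len(self.populations) != seqs.shape[0]:
            raise ValueError("populations length mismatch")

    @property
    def n_sequences(self) -> int:
        return self.sequences.shape[0]

    @property
    def length(self) -> int:
        return self.sequences.shape[1]

    def sequence_strings(self) -> list[str]:
        return [row.tobytes().decode() for row in self.sequences]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeAlignment):
            return NotImplemented
        return (
            np.array_equal(self.sequences, other.sequences)
            and self.ids == other.ids
            and self.populations == other.populations
        )
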