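"""Coalescent simulation under piecewise-constant Ne.

Two simulation routes are provided, both exact samples from the same
process:

* an explicit-genealogy route (:func:`simulate_genealogy` plus per-locus
  mutation placement) used for mtDNA alignments and for validation;
* a vectorised allele-frequency route (:func:`simulate_locus_counts_batch`)
  that never builds topologies. It exploits two classical facts about the
  n-coalescent: (i) after rescaling time by ``1 / (ploidy_scale * Ne(t))``
  the inter-coalescence waiting times are iid ``Exp(k(k-1)/2)``, so event
  times under any piecewise-constant history are obtained by mapping
  standard-coalescent times through the piecewise-linear inverse of the
  rescaling; and (ii) conditional on a mutation falling in the interval
  with ``k`` ancestral lineages, the number ``i`` of sampled copies that
  inherit it follows ``P(i) = C(m-i-1, k-2) / C(m-1, k-1)`` for a sample of
  ``m`` copies (the size of one part of a uniform composition of ``m`` into
  ``k`` parts). Sampling the derived-allele count this way, then assigning
  carriers uniformly at random, reproduces the joint genotype distribution
  of the genealogy route for unlinked loci by exchangeability.

Mutation model for SNP loci: the number of mutations on a genealogy is
Poisson(rate x total branch length); polymorphic loci retain exactly one
mutation, chosen uniformly along the branches, mirroring the
one-SNP-per-locus usage of the RAD data. Loci with zero mutations are
monomorphic, which keeps the "proportion of monomorphic loci" summary
statistic informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .datatypes import MISSING, HaplotypeAlignment, SNPDataset
from .demographic_models import DemographicScenario

__all__ = [
    "Genealogy",
    "simulate_genealogy",
    "simulate_snp_locus",
    "simulate_snp_dataset",
    "simulate_locus_counts_batch",
    "simulate_mtdna_alignment",
    "simulate_neutral_genealogy_stats",
    "DIPLOID_SCALE",
    "MTDNA_SCALE",
    "DEFAULT_LOCUS_MUTATION_RATE",
    "DEFAULT_CLOCK_RATE",
]

#: gene copies per unit of diploid Ne for autosomal loci (2N copies)
DIPLOID_SCALE = 2.0
#: mitochondrial effective copies per unit of diploid Ne (haploid, maternal: N/4)
MTDNA_SCALE = 0.25
#: default per-locus per-generation SNP mutation rate
#: (~115 bp RAD locus x ~2.2e-9 per site per generation)
DEFAULT_LOCUS_MUTATION_RATE = 2.5e-7
#: default mtDNA clock, substitutions/site/Myr on the divergence
#: (between-lineage) scale; the per-lineage rate is half of this
DEFAULT_CLOCK_RATE = 0.021


@dataclass
class Genealogy:
    """A coalescent tree for ``n_tips`` gene copies.

    Nodes ``0..n_tips-1`` are tips at time 0; internal nodes are appended
    in coalescence order. ``parent[root] == -1``.
    """

    parent: np.ndarray
    node_times: np.ndarray
    n_tips: int

    def __post_init__(self) -> None:
        if self.n_tips < 1:
            raise ValueError("n_tips must be >= 1")
        n_nodes = 2 * self.n_tips - 1
        if len(self.parent) != n_nodes or len(self.node_times) != n_nodes:
            raise ValueError("parent/node_times must have 2*n_tips-1 entries")

    @property
    def total_branch_length(self) -> float:
        """Sum over non-root branches of (parent time - child time), generations."""
        if self.n_tips == 1:
            return 0.0
        has_parent = self.parent >= 0
        return float(
            np.sum(self.node_times[self.parent[has_parent]] - self.node_times[has_parent])
        )

    def branch_lengths(self) -> np.ndarray:
        """Per-node branch length to the parent (0 for the root)."""
        lengths = np.zeros(len(self.parent))
        has_parent = self.parent >= 0
        lengths[has_parent] = (
            self.node_times[self.parent[has_parent]] - self.node_times[has_parent]
        )
        return lengths

    def descendant_matrix(self) -> np.ndarray:
        """Boolean ``(n_nodes, n_tips)`` matrix of tip descendants."""
        n_nodes = len(self.parent)
        desc = np.zeros((n_nodes, self.n_tips), dtype=bool)
        desc[np.arange(self.n_tips), np.arange(self.n_tips)] = True
        # children always have lower index than their parent
        for child in range(n_nodes - 1):
            desc[self.parent[child]] |= desc[child]
        return desc


class _TimeRescaling:
    """Map between generations and standard-coalescent time for a history."""

    def __init__(self, demography: DemographicScenario, ploidy_scale: float):
        if ploidy_scale <= 0:
            raise ValueError("ploidy_scale must be positive")
        self.starts = demography.start_times.astype(float)
        self.copies = ploidy_scale * demography.sizes.astype(float)
        gaps = np.diff(self.starts)
        self.tau_bounds = np.concatenate([[0.0], np.cumsum(gaps / self.copies[:-1])])

    def time_of_tau(self, tau: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.tau_bounds, tau, side="right") - 1
        return self.starts[idx] + (tau - self.tau_bounds[idx]) * self.copies[idx]


def simulate_genealogy(
    n_copies: int,
    demography: DemographicScenario,
    ploidy_scale: float = DIPLOID_SCALE,
    rng: np.random.Generator | None = None,
) -> Genealogy:
    """Simulate one gene genealogy under a piecewise-constant history.

    With ``k`` lineages in an epoch of diploid size ``N``, the waiting time
    to the next coalescence is exponential with rate
    ``k(k-1)/2 / (ploidy_scale * N)`` per generation; epoch boundaries are
    handled by the standard time-rescaling construction.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    n_nodes = 2 * n_copies - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    times = np.zeros(n_nodes)
    if n_copies == 1:
        return Genealogy(parent=parent, node_times=times, n_tips=1)

    k_values = np.arange(n_copies, 1, -1)
    rates = k_values * (k_values - 1) / 2.0
    tau_events = np.cumsum(rng.standard_exponential(n_copies - 1) / rates)
    t_events = _TimeRescaling(demography, ploidy_scale).time_of_tau(tau_events)

    active = list(range(n_copies))
    for e, t in enumerate(t_events):
        node = n_copies + e
        i = rng.integers(len(active))
        a = active.pop(i)
        j = rng.integers(len(active))
        b = active.pop(j)
        parent[a] = node
        parent[b] = node
        times[node] = t
        active.append(node)
    return Genealogy(parent=parent, node_times=times, n_tips=n_copies)


def simulate_snp_locus(
    genealogy: Genealogy,
    locus_mutation_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Derived-allele indicator per gene copy for one unlinked SNP locus.

    Mutation count is Poisson(rate x total branch length); if at least one
    mutation occurs, a single mutation is retained (uniformly over branch
    length) and every copy below the mutated branch carries the derived
    allele. Returns all zeros for a monomorphic locus.
    """
    if locus_mutation_rate < 0:
        raise ValueError("locus_mutation_rate must be >= 0")
    m = genealogy.n_tips
    total = genealogy.total_branch_length
    if total == 0 or rng.poisson(locus_mutation_rate * total) == 0:
        return np.zeros(m, dtype=np.uint8)
    lengths = genealogy.branch_lengths()
    u = rng.random() * total
    node = int(np.searchsorted(np.cumsum(lengths), u, side="right"))
    return genealogy.descendant_matrix()[node].astype(np.uint8)


@lru_cache(maxsize=16)
def _descendant_count_cdfs(m: int) -> np.ndarray:
    """CDF of derived-copy counts, per lineage level.

    Row ``k-2`` holds the CDF of ``P(i | k) = C(m-i-1, k-2) / C(m-1, k-1)``
    over ``i = 1..m-k+1`` (entries beyond the support are 1).
    """
    lg = gammaln(np.arange(m + 1) + 1.0)

    def log_binom(n: np.ndarray, k: np.ndarray) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        k = np.asarray(k, dtype=float)
        with np.errstate(invalid="ignore"):
            out = np.where(
                (k >= 0) & (k <= n),
                lg[np.clip(n, 0, m).astype(int)]
                - lg[np.clip(k, 0, m).astype(int)]
                - lg[np.clip(n - k, 0, m).astype(int)],
                -np.inf,
            )
        return out

    ks = np.arange(2, m + 1)
    i = np.arange(1, m)
    logp = log_binom(m - i[None, :] - 1, ks[:, None] - 2) - log_binom(
        np.full_like(ks, m - 1)[:, None], ks[:, None] - 1
    )
    pmf = np.exp(logp)
    cdf = np.cumsum(pmf, axis=1)
    return np.minimum(cdf, 1.0)


def _epoch_arrays(
    demography: DemographicScenario | None,
    starts: np.ndarray | None,
    sizes: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    if demography is not None:
        return demography.start_times[None, :], demography.sizes[None, :]
    return np.atleast_2d(starts), np.atleast_2d(sizes)


def simulate_locus_counts_batch(
    n_copies: int,
    n_loci: int,
    rng: np.random.Generator,
    demography: DemographicScenario | None = None,
    epoch_starts: np.ndarray | None = None,
    epoch_sizes: np.ndarray | None = None,
    locus_mutation_rate: float = DEFAULT_LOCUS_MUTATION_RATE,
    ploidy_scale: float = DIPLOID_SCALE,
) -> np.ndarray:
    """Derived-allele counts for unlinked loci, vectorised over loci and sims.

    Either ``demography`` (single history) or ``epoch_starts``/``epoch_sizes``
    arrays of shape ``(B, n_epochs)`` in generations/diploid individuals
    (padded on the right by repeating the last epoch) may be given. Returns
    an integer array of shape ``(B, n_loci)``; 0 means monomorphic.
    """
    if n_copies < 2:
        raise ValueError("n_copies must be >= 2")
    if locus_mutation_rate < 0:
        raise ValueError("locus_mutation_rate must be >= 0")
    starts, sizes = _epoch_arrays(demography, epoch_starts, epoch_sizes)
    if np.any(sizes <= 0):
        raise ValueError("all epoch sizes must be positive")
    B, E = starts.shape
    m = n_copies

    k_vec = np.arange(m, 1, -1, dtype=float)
    rates = k_vec * (k_vec - 1) / 2.0
    tau = np.cumsum(rng.standard_exponential((B, n_loci, m - 1)) / rates, axis=2)

    copies = ploidy_scale * sizes
    tau_bounds = np.zeros((B, E))
    if E > 1:
        tau_bounds[:, 1:] = np.cumsum(np.diff(starts, axis=1) / copies[:, :-1], axis=1)

    idx = np.zeros(tau.shape, dtype=np.int64)
    for j in range(1, E):
        idx += tau >= tau_bounds[:, j, None, None]
    b_idx = np.arange(B)[:, None, None]
    t = starts[b_idx, idx] + (tau - tau_bounds[b_idx, idx]) * copies[b_idx, idx]

    durations = np.diff(t, axis=2, prepend=0.0)
    weights = k_vec * durations
    total_length = weights.sum(axis=2)

    p_poly = -np.expm1(-locus_mutation_rate * total_length)
    is_poly = rng.random((B, n_loci)) < p_poly

    # level (number of extant lineages) of the retained mutation
    cum_w = np.cumsum(weights, axis=2)
    u_pos = rng.random((B, n_loci)) * total_length
    level_idx = (cum_w < u_pos[..., None]).sum(axis=2)
    k_sel = m - level_idx  # k lineages during the mutated interval

    counts = np.zeros((B, n_loci), dtype=np.int64)
    cdfs = _descendant_count_cdfs(m)
    u_cnt = rng.random((B, n_loci))
    flat_poly = is_poly.ravel()
    flat_k = k_sel.ravel()[flat_poly]
    flat_u = u_cnt.ravel()[flat_poly]
    flat_counts = np.empty(flat_k.shape, dtype=np.int64)
    for k in np.unique(flat_k):
        sel = flat_k == k
        flat_counts[sel] = np.searchsorted(cdfs[k - 2], flat_u[sel], side="right") + 1
    out = counts.ravel()
    out[np.flatnonzero(flat_poly)] = flat_counts
    return out.reshape(B, n_loci)


def _counts_to_genotypes(
    counts: np.ndarray, n_individuals: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign derived copies uniformly and pair copies into diploids."""
    n_loci = counts.shape[0]
    m = 2 * n_individuals
    ranks = np.argsort(rng.random((n_loci, m)), axis=1, kind="stable")
    carrier = ranks < counts[:, None]
    genotypes = carrier[:, 0::2].astype(np.int8) + carrier[:, 1::2].astype(np.int8)
    return genotypes.T  # individuals x loci


def simulate_snp_dataset(
    n_individuals: int,
    n_loci: int,
    demography: DemographicScenario,
    locus_mutation_rate: float = DEFAULT_LOCUS_MUTATION_RATE,
    missing_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    method: str = "counts",
) -> SNPDataset:
    """Simulate a diploid SNP dataset of unlinked loci.

    ``method="counts"`` uses the vectorised frequency route;
    ``method="genealogy"`` builds one explicit genealogy per locus. Both
    sample the same process (see module docstring).
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    if not 0 <= missing_rate <= 1:
        raise ValueError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    m = 2 * n_individuals

    if method == "counts":
        counts = simulate_locus_counts_batch(
            m, n_loci, rng, demography=demography, locus_mutation_rate=locus_mutation_rate
        )[0]
        genotypes = _counts_to_genotypes(counts, n_individuals, rng)
    elif method == "genealogy":
        genotypes = np.empty((n_individuals, n_loci), dtype=np.int8)
        for j in range(n_loci):
            tree = simulate_genealogy(m, demography, rng=rng)
            copies = simulate_snp_locus(tree, locus_mutation_rate, rng)
            copies = copies[rng.permutation(m)]  # random pairing into diploids
            genotypes[:, j] = copies[0::2] + copies[1::2]
    else:
        raise ValueError(f"unknown method {method!r}")

    if missing_rate > 0:
        mask = rng.random(genotypes.shape) < missing_rate
        genotypes = np.where(mask, np.int8(MISSING), genotypes)
    return SNPDataset(genotypes=genotypes)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_mtdna_alignment(
    n_samples: int,
    length_bp: int,
    demography: DemographicScenario,
    clock_rate: float = DEFAULT_CLOCK_RATE,
    rng: np.random.Generator | None = None,
    generation_time: float = 1.0,
    mtdna_scale: float = MTDNA_SCALE,
) -> HaplotypeAlignment:
    """Simulate an mtDNA alignment under a strict molecular clock.

    ``clock_rate`` is the divergence (between-lineage) substitution rate in
    substitutions/site/Myr; the per-lineage rate is half of it. The
    mitochondrial genealogy runs at ``mtdna_scale`` effective copies per
    diploid individual (default N/4: haploid and maternally inherited).
    Mutations are Poisson on branches, each hitting a uniformly random
    site; repeat hits at a site are resolved last-mutation-wins.
    """
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if clock_rate < 0:
        raise ValueError("clock_rate must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    per_lineage_site_gen = 0.5 * clock_rate * 1e-6 * generation_time

    tree = simulate_genealogy(n_samples, demography, ploidy_scale=mtdna_scale, rng=rng)
    ancestral = _BASES[rng.integers(4, size=length_bp)]
    seqs = np.tile(ancestral, (n_samples, 1))
    if per_lineage_site_gen == 0 or n_samples == 1:
        return HaplotypeAlignment(sequences=seqs)

    lengths = tree.branch_lengths()
    n_mut = rng.poisson(per_lineage_site_gen * lengths * length_bp)
    if n_mut.sum() == 0:
        return HaplotypeAlignment(sequences=seqs)

    desc = tree.descendant_matrix()
    nodes = np.repeat(np.arange(len(lengths)), n_mut)
    ages = tree.node_times[nodes] + rng.random(nodes.size) * lengths[nodes]
    sites = rng.integers(length_bp, size=nodes.size)
    # new base: uniformly one of the three bases differing from the ancestral
    shifts = rng.integers(1, 4, size=nodes.size)
    order = np.argsort(-ages)  # oldest first; younger mutations overwrite
    for node, site, shift in zip(nodes[order], sites[order], shifts[order]):
        anc_idx = int(np.searchsorted(_BASES, ancestral[site]))
        new_base = _BASES[(anc_idx + shift) % 4]
        seqs[desc[node], site] = new_base
    return HaplotypeAlignment(sequences=seqs)


def simulate_neutral_genealogy_stats(
    n: int,
    theta: float,
    rng: np.random.Generator,
) -> tuple[int, float, int]:
    """(S, mean pairwise differences, haplotype count) under constant size.

    Standard constant-size coalescent in rescaled time with infinite-sites
    mutation at rate ``theta/2`` per lineage per coalescent time unit; used
    as the null for the neutrality tests.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if theta <= 0:
        raise ValueError("theta must be positive")
    const = DemographicScenario(scenario_id=1, epochs=((0.0, 1.0),))
    tree = simulate_genealogy(n, const, ploidy_scale=1.0, rng=rng)  # rate C(k,2) per unit
    lengths = tree.branch_lengths()
    n_mut = rng.poisson(0.5 * theta * lengths)
    S = int(n_mut.sum())
    if S == 0:
        return 0, 0.0, 1
    desc = tree.descendant_matrix()
    counts = np.repeat(desc[: len(lengths)].sum(axis=1), n_mut)
    pi_total = float(np.sum(counts * (n - counts)) / (n * (n - 1) / 2))
    site_matrix = np.repeat(desc[np.flatnonzero(n_mut)], n_mut[n_mut > 0], axis=0)
    n_haplotypes = len(np.unique(site_matrix.T, axis=0))
    return S, pi_total, n_haplotypes
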