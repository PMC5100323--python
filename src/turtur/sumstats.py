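"""Summary statistics: SNP gene diversity and mtDNA diversity/neutrality.

The four SNP statistics are the single-population summaries the ABC step
conditions on: proportion of monomorphic loci, mean and variance of gene
diversity across polymorphic loci, and mean gene diversity across all
loci. Gene diversity uses Nei's unbiased estimator with the number of
non-missing gene copies at each locus.

mtDNA statistics follow the conventions of the classical sequence-analysis
tools: alignment columns containing a gap or ambiguity code are removed
entirely before anything is counted (complete deletion; a pairwise-deletion
variant of nucleotide diversity is available behind a flag). Tajima's D and
Fu's Fs are the two neutrality tests; both go negative under a recent
population expansion. Fu's Fs is computed from the Ewens sampling formula
with unsigned Stirling numbers of the first kind evaluated in log space, so
it remains finite-precision-safe at large sample sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from .coalescent_sim import simulate_neutral_genealogy_stats
from .datatypes import HaplotypeAlignment, SNPDataset

__all__ = [
    "SnpSummaryStats",
    "MtdnaStats",
    "NoSegregationError",
    "STAT_NAMES",
    "gene_diversity",
    "gene_diversity_from_counts",
    "snp_summary_stats",
    "snp_stats_from_counts",
    "mtdna_basic_stats",
    "mtdna_stats",
    "tajimas_d",
    "fus_fs",
    "neutrality_significance",
]

#: fixed ordering of the SNP summary statistics (distance computations rely on it)
STAT_NAMES = ("prop_monomorphic", "mean_gd_poly", "var_gd_poly", "mean_gd_all")


class NoSegregationError(ValueError):
    """Raised when a statistic is undefined because S = 0."""


@dataclass(frozen=True)
class SnpSummaryStats:
    """The four single-population SNP summaries, in :data:`STAT_NAMES` order."""

    prop_monomorphic: float
    mean_gd_poly: float
    var_gd_poly: float
    mean_gd_all: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.prop_monomorphic, self.mean_gd_poly, self.var_gd_poly, self.mean_gd_all]
        )


@dataclass(frozen=True)
class MtdnaStats:
    """Diversity and neutrality statistics for an mtDNA alignment."""

    n_sequences: int
    retained_length: int
    S: int
    n_haplotypes: int
    Hd: float
    pi: float
    pi_total: float
    tajimas_D: float | None = None
    fus_Fs: float | None = None


def gene_diversity_from_counts(derived: np.ndarray, copies: np.ndarray) -> np.ndarray:
    """Nei's unbiased gene diversity per locus from allele counts.

    ``H = n/(n-1) * (1 - p^2 - q^2)`` with ``n`` non-missing gene copies.
    Loci with fewer than 2 copies yield NaN.
    """
    derived = np.asarray(derived, dtype=float)
    copies = np.asarray(copies, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = derived / copies
        h = copies / (copies - 1.0) * (1.0 - p**2 - (1.0 - p) ** 2)
    return np.where(copies >= 2, h, np.nan)


def gene_diversity(genotype_column: np.ndarray) -> float:
    """Gene diversity for one locus from diploid doses (missing = -1)."""
    g = np.asarray(genotype_column)
    called = g >= 0
    copies = 2 * int(called.sum())
    if copies < 2:
        raise ValueError("gene diversity needs >= 2 non-missing gene copies")
    derived = int(g[called].sum())
    return float(gene_diversity_from_counts(np.array([derived]), np.array([copies]))[0])


def snp_stats_from_counts_batch(
    derived: np.ndarray, copies: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised four-statistic computation over a batch of datasets.

    ``derived`` and ``copies`` have shape ``(B, n_loci)``. Returns a
    ``(B, 4)`` array in :data:`STAT_NAMES` order plus a boolean mask of
    degenerate rows (fewer than two polymorphic loci, so the across-locus
    variance is undefined). Loci with fewer than 2 non-missing copies are
    excluded per row.
    """
    derived = np.atleast_2d(derived).astype(float)
    copies = np.atleast_2d(copies).astype(float)
    usable = copies >= 2
    n_usable = usable.sum(axis=1)
    if np.any(n_usable == 0):
        raise ValueError("no locus with >= 2 non-missing gene copies")
    poly = (derived > 0) & (derived < copies) & usable
    n_poly = poly.sum(axis=1)

    h = np.where(usable, gene_diversity_from_counts(derived, copies), 0.0)
    h_poly = np.where(poly, h, 0.0)
    prop_mono = 1.0 - n_poly / n_usable
    mean_all = h_poly.sum(axis=1) / n_usable
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_poly = np.where(n_poly > 0, h_poly.sum(axis=1) / n_poly, np.nan)
        ss = np.where(poly, (h - mean_poly[:, None]) ** 2, 0.0).sum(axis=1)
        var_poly = np.where(n_poly > 1, ss / np.maximum(n_poly - 1, 1), np.nan)
    stats = np.column_stack([prop_mono, mean_poly, var_poly, mean_all])
    return stats, n_poly < 2


def snp_stats_from_counts(derived: np.ndarray, copies: np.ndarray) -> SnpSummaryStats:
    """Compute the four summaries from per-locus (derived, total) copy counts.

    Loci with fewer than 2 non-missing copies are excluded. A locus is
    monomorphic iff one allele has frequency 1 among the non-missing copies.
    """
    stats, degenerate = snp_stats_from_counts_batch(
        np.asarray(derived)[None, :], np.asarray(copies)[None, :]
    )
    return SnpSummaryStats(*stats[0], degenerate=bool(degenerate[0]))


def snp_summary_stats(dataset: SNPDataset) -> SnpSummaryStats:
    """The four ABC summary statistics for a SNP dataset."""
    derived, copies = dataset.allele_counts()
    return snp_stats_from_counts(derived, copies)


def _retained_columns(seqs: np.ndarray) -> np.ndarray:
    """Complete deletion: keep columns where every sequence has A/C/G/T."""
    valid = np.isin(seqs, np.frombuffer(b"ACGT", dtype=np.uint8))
    return valid.all(axis=0)


def mtdna_basic_stats(
    aln: HaplotypeAlignment, deletion: str = "complete"
) -> MtdnaStats:
    """Segregating sites, haplotype and nucleotide diversity of an alignment.

    ``deletion="complete"`` (default) drops any column containing a gap or
    ambiguous base before all computations; ``"pairwise"`` computes
    nucleotide diversity on pairwise-complete sites instead (S, haplotype
    counts and Hd still use complete deletion, where haplotype identity is
    well defined).
    """
    if aln.n_sequences < 2:
        raise ValueError("need >= 2 sequences")
    seqs = aln.sequences
    n = aln.n_sequences
    keep = _retained_columns(seqs)
    L = int(keep.sum())
    if L == 0:
        raise ValueError("no alignment columns left after complete deletion")
    retained = seqs[:, keep]

    n_distinct = np.array([len(np.unique(retained[:, j])) for j in range(L)])
    S = int((n_distinct > 1).sum())
    haplos, hap_index = np.unique(retained, axis=0, return_inverse=True)
    k_obs = haplos.shape[0]
    freqs = np.bincount(hap_index) / n
    Hd = float(n / (n - 1) * (1.0 - np.sum(freqs**2)))

    n_pairs = n * (n - 1) / 2
    if deletion == "complete":
        # per-site pair-difference counting via allele counts
        diffs = 0.0
        for j in np.flatnonzero(n_distinct > 1):
            _, counts = np.unique(retained[:, j], return_counts=True)
            diffs += n_pairs - np.sum(counts * (counts - 1) / 2)
        pi_total = float(diffs / n_pairs)
        pi = pi_total / L
    elif deletion == "pairwise":
        valid = np.isin(seqs, np.frombuffer(b"ACGT", dtype=np.uint8))
        per_pair = []
        for i in range(n - 1):
            both = valid[i] & valid[i + 1 :]
            mism = (seqs[i] != seqs[i + 1 :]) & both
            sites = both.sum(axis=1).astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                per_pair.append(np.where(sites > 0, mism.sum(axis=1) / sites, np.nan))
        pi = float(np.nanmean(np.concatenate(per_pair)))
        pi_total = pi * L
    else:
        raise ValueError(f"unknown deletion mode {deletion!r}")

    return MtdnaStats(
        n_sequences=n,
        retained_length=L,
        S=S,
        n_haplotypes=k_obs,
        Hd=Hd,
        pi=pi,
        pi_total=pi_total,
    )


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(S: int, n: int, pi_total: float) -> float:
    """Tajima's D from segregating sites and mean pairwise differences."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S < 1:
        raise NoSegregationError("Tajima's D is undefined when S = 0")
    a1 = sum(1.0 / i for i in range(1, n))
    e1, e2 = _tajima_constants(n)
    return float((pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1)))


@lru_cache(maxsize=8)
def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned first kind), via the DP
    s(n,k) = s(n-1,k-1) + (n-1) s(n-1,k) evaluated in log space."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # s(0,0) = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        new[1 : m + 1] = np.logaddexp(row[0:m], math.log(m - 1) + row[1 : m + 1] if m > 1 else -np.inf)
        row = new
    return row


def _ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k | theta, n) for k = 1..n under the Ewens sampling formula."""
    log_s = _log_stirling_row(n)[1:]
    k = np.arange(1, n + 1)
    log_rising = np.sum(np.log(theta + np.arange(n)))
    return log_s + k * math.log(theta) - log_rising


def fus_fs(n: int, k_obs: int, theta: float) -> float:
    """Fu's Fs: logit of S' = P(K >= k_obs) under the Ewens formula.

    ``theta`` is conventionally the mean number of pairwise differences.
    Returns signed infinity (with a warning) when S' is numerically 0 or 1.
    """
    if n < 2:
        raise ValueError("Fu's Fs needs n >= 2")
    if not 1 <= k_obs <= n:
        raise ValueError("k_obs must be in 1..n")
    if theta <= 0:
        raise ValueError("theta must be positive")
    logp = _ewens_log_pmf(n, theta)
    log_upper = logsumexp(logp[k_obs - 1 :])
    if k_obs == 1:
        warnings.warn("S' = 1 (every k_obs >= 1): Fs is +inf", RuntimeWarning, stacklevel=2)
        return math.inf
    log_lower = logsumexp(logp[: k_obs - 1])
    if not np.isfinite(log_upper):
        warnings.warn("S' underflowed to 0: Fs is -inf", RuntimeWarning, stacklevel=2)
        return -math.inf
    if not np.isfinite(log_lower):
        warnings.warn("S' is numerically 1: Fs is +inf", RuntimeWarning, stacklevel=2)
        return math.inf
    return float(log_upper - log_lower)


def mtdna_stats(aln: HaplotypeAlignment, deletion: str = "complete") -> MtdnaStats:
    """Basic diversity statistics plus Tajima's D and Fu's Fs."""
    base = mtdna_basic_stats(aln, deletion=deletion)
    D = tajimas_d(base.S, base.n_sequences, base.pi_total) if base.S >= 1 else None
    Fs = (
        fus_fs(base.n_sequences, base.n_haplotypes, base.pi_total)
        if base.pi_total > 0
        else None
    )
    return MtdnaStats(
        n_sequences=base.n_sequences,
        retained_length=base.retained_length,
        S=base.S,
        n_haplotypes=base.n_haplotypes,
        Hd=base.Hd,
        pi=base.pi,
        pi_total=base.pi_total,
        tajimas_D=D,
        fus_Fs=Fs,
    )


def _null_statistic(statistic: str, n: int, S: int, pi_total: float, k: int) -> float:
    if statistic == "D":
        return tajimas_d(S, n, pi_total) if S >= 1 else 0.0
    if S == 0 or pi_total == 0:
        return math.inf  # single haplotype: S' = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fus_fs(n, k, pi_total)


def neutrality_significance(
    aln: HaplotypeAlignment,
    statistic: str = "D",
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Lower-tail p-value for Tajima's D or Fu's Fs by coalescent null simulation.

    The null distribution is generated by constant-size coalescent
    simulation with theta estimated from the observed mean pairwise
    differences (the procedure behind the "permutation" significance of the
    classical tools). ``p = (1 + #{null <= observed}) / (n + 1)``.
    """
    if statistic not in ("D", "Fs"):
        raise ValueError("statistic must be 'D' or 'Fs'")
    if n_permutations < 100:
        warnings.warn("fewer than 100 null replicates: p-value will be coarse", stacklevel=2)
    rng = np.random.default_rng() if rng is None else rng
    obs_stats = mtdna_stats(aln)
    if obs_stats.pi_total <= 0:
        raise NoSegregationError("no variation in the alignment")
    observed = obs_stats.tajimas_D if statistic == "D" else obs_stats.fus_Fs
    n = obs_stats.n_sequences
    theta = obs_stats.pi_total
    count = 0
    for _ in range(n_permutations):
        S, pi_total, k = simulate_neutral_genealogy_stats(n, theta, rng)
        if _null_statistic(statistic, n, S, pi_total, k) <= observed:
            count += 1
    return (1 + count) / (n_permutations + 1)
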