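"""Population-structure diagnostics: hierarchical AMOVA and genotype PCA.

The AMOVA follows the squared-distance sums-of-squares decomposition of
Excoffier, Smouse & Quattro: for any set of units the sum of squares is
``SS = (1/n) * sum_{i<j} d2_ij``, and the nested decomposition (groups /
populations within groups / individuals within populations / within
individuals) yields variance components through the standard
unequal-sample-size nested-ANOVA coefficients. Diploid SNP data are
expanded to gene copies (allele mismatch distances, pairwise-complete over
loci; the expansion is phase-free because every sum of squares aggregates
over all copy pairs). mtDNA alignments run the three-level haplotypic
decomposition on pairwise nucleotide differences.

Significance uses the level-appropriate permutation schemes: whole
populations among groups for Phi_CT, individuals among populations within
groups for Phi_SC, gene copies among individuals within populations for
Phi_IS. Negative variance-component estimates are retained (not truncated),
matching the convention of the classical AMOVA software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import HaplotypeAlignment, SNPDataset

__all__ = [
    "GroupingScheme",
    "AMOVAResult",
    "amova",
    "pca_genotypes",
    "weir_cockerham_fst",
]


@dataclass
class GroupingScheme:
    """sample -> population (locality) -> group (flyway) mapping."""

    population: dict[str, str]
    group_of_population: dict[str, str]

    def __post_init__(self) -> None:
        pops = set(self.population.values())
        unmapped = pops - set(self.group_of_population)
        if unmapped:
            raise ValueError(f"populations without a group: {sorted(unmapped)}")

    @classmethod
    def from_table(cls, samples, populations, groups) -> "GroupingScheme":
        pop = dict(zip(samples, populations))
        gop: dict[str, str] = {}
        for p, g in zip(populations, groups):
            if gop.setdefault(p, g) != g:
                raise ValueError(f"population {p} mapped to more than one group")
        return cls(population=pop, group_of_population=gop)

    @classmethod
    def from_tsv(cls, path) -> "GroupingScheme":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population", "group"],
                         dtype=str, comment="#")
        return cls.from_table(df["sample"], df["population"], df["group"])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for sample, pop in self.population.items():
                fh.write(f"{sample}\t{pop}\t{self.group_of_population[pop]}\n")

    def labels_for(self, ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        missing = [s for s in ids if s not in self.population]
        if missing:
            raise ValueError(f"samples not in the grouping scheme: {missing[:5]}")
        pops = np.array([self.population[s] for s in ids])
        groups = np.array([self.group_of_population[p] for p in pops])
        return pops, groups


@dataclass
class AMOVAResult:
    """Variance decomposition, Phi-statistics and permutation p-values."""

    components: pd.DataFrame  # level, df, SS, variance, pct_variance
    phi: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)


def _set_ss(D: np.ndarray, members: np.ndarray) -> float:
    """SS of a unit set from the full ordered-pair squared-distance sum."""
    block = D[np.ix_(members, members)].sum()
    return block / (2.0 * len(members))


def _three_level_components(
    D: np.ndarray, pops: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(df array, variance components [a, b, c], notes) for units/pops/groups."""
    n = len(pops)
    uniq_pops = np.unique(pops)
    uniq_groups = np.unique(groups)
    P, G = len(uniq_pops), len(uniq_groups)
    if G < 2 or P < 2:
        raise ValueError("hierarchical AMOVA needs >= 2 groups and >= 2 populations")

    ss_total = D.sum() / (2.0 * n)
    ss_groups = sum(_set_ss(D, np.flatnonzero(groups == g)) for g in uniq_groups)
    ss_pops = sum(_set_ss(D, np.flatnonzero(pops == p)) for p in uniq_pops)
    ssd = np.array([ss_total - ss_groups, ss_groups - ss_pops, ss_pops])
    df = np.array([G - 1, P - G, n - P], dtype=float)

    n_p = np.array([(pops == p).sum() for p in uniq_pops], dtype=float)
    group_of_pop = np.array([groups[pops == p][0] for p in uniq_pops])
    n_g = np.array([(groups == g).sum() for g in uniq_groups], dtype=float)
    sum_np2_by_group = np.array(
        [np.sum(n_p[group_of_pop == g] ** 2) for g in uniq_groups]
    )
    notes: list[str] = []
    coef_n = (n - np.sum(sum_np2_by_group / n_g)) / (P - G) if P > G else np.nan
    coef_np = (np.sum(sum_np2_by_group / n_g) - np.sum(n_p**2) / n) / (G - 1)
    coef_ng = (n - np.sum(n_g**2) / n) / (G - 1)

    ms = np.where(df > 0, ssd / np.where(df > 0, df, 1.0), np.nan)
    sigma_c = ms[2]
    sigma_b = (ms[1] - sigma_c) / coef_n if P > G else np.nan
    if P == G:
        notes.append("every group has a single population: Phi_SC undefined")
    sigma_a = (ms[0] - sigma_c - coef_np * (0.0 if np.isnan(sigma_b) else sigma_b)) / coef_ng
    return df, np.array([sigma_a, sigma_b, sigma_c]), notes


def _four_level_components(
    D: np.ndarray,
    copy_ind: np.ndarray,
    copy_pop: np.ndarray,
    copy_group: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(df, [sigma_a, sigma_b, sigma_c, sigma_d], notes) at gene-copy level."""
    C = len(copy_ind)
    uniq_inds = np.unique(copy_ind)
    uniq_pops = np.unique(copy_pop)
    uniq_groups = np.unique(copy_group)
    N, P, G = len(uniq_inds), len(uniq_pops), len(uniq_groups)
    if G < 2 or P < 2:
        raise ValueError("hierarchical AMOVA needs >= 2 groups and >= 2 populations")

    ss_total = D.sum() / (2.0 * C)
    ss_groups = sum(_set_ss(D, np.flatnonzero(copy_group == g)) for g in uniq_groups)
    ss_pops = sum(_set_ss(D, np.flatnonzero(copy_pop == p)) for p in uniq_pops)
    ss_inds = sum(_set_ss(D, np.flatnonzero(copy_ind == i)) for i in uniq_inds)
    ssd = np.array(
        [ss_total - ss_groups, ss_groups - ss_pops, ss_pops - ss_inds, ss_inds]
    )
    df = np.array([G - 1, P - G, N - P, N], dtype=float)

    # copies per pop / group (c_i = 2 everywhere, so several coefficients are 2)
    C_p = np.array([(copy_pop == p).sum() for p in uniq_pops], dtype=float)
    group_of_pop = np.array([copy_group[copy_pop == p][0] for p in uniq_pops])
    C_g = np.array([(copy_group == g).sum() for g in uniq_groups], dtype=float)
    sum_Cp2_by_group = np.array(
        [np.sum(C_p[group_of_pop == g] ** 2) for g in uniq_groups]
    )
    notes: list[str] = []
    n3 = (C - np.sum(sum_Cp2_by_group / C_g)) / (P - G) if P > G else np.nan
    n5 = (np.sum(sum_Cp2_by_group / C_g) - np.sum(C_p**2) / C) / (G - 1)
    n6 = (C - np.sum(C_g**2) / C) / (G - 1)

    ms = np.where(df > 0, ssd / np.where(df > 0, df, 1.0), np.nan)
    sigma_d = ms[3]
    sigma_c = (ms[2] - sigma_d) / 2.0
    sigma_b = (ms[1] - sigma_d - 2.0 * sigma_c) / n3 if P > G else np.nan
    if P == G:
        notes.append("every group has a single population: Phi_SC undefined")
    sigma_a = (
        ms[0] - sigma_d - 2.0 * sigma_c - n5 * (0.0 if np.isnan(sigma_b) else sigma_b)
    ) / n6
    return df, np.array([sigma_a, sigma_b, sigma_c, sigma_d]), notes


def _phi_from_components(sig: np.ndarray) -> dict[str, float]:
    total = np.nansum(sig)
    if total == 0:
        return {}
    def _ratio(num, den):
        return num / den if den != 0 else np.nan
    if len(sig) == 4:
        a, b, c, d = sig
        return {
            "Phi_CT": a / total,
            "Phi_SC": _ratio(b, b + c + d) if not np.isnan(b) else np.nan,
            "Phi_IS": _ratio(c, c + d),
            "Phi_IT": (a + (0.0 if np.isnan(b) else b) + c) / total,
        }
    a, b, c = sig
    return {
        "Phi_CT": a / total,
        "Phi_SC": _ratio(b, b + c) if not np.isnan(b) else np.nan,
        "Phi_ST": (a + (0.0 if np.isnan(b) else b)) / total,
    }


def _snp_copy_matrix(dataset: SNPDataset) -> tuple[np.ndarray, np.ndarray]:
    """Phase-arbitrary gene-copy allele matrix (2N x L) and validity mask."""
    g = dataset.genotypes
    n, L = g.shape
    X = np.zeros((2 * n, L))
    V = np.zeros((2 * n, L))
    called = g >= 0
    dose = np.where(called, g, 0)
    X[0::2] = (dose >= 1).astype(float)  # first copy carries the derived allele if any
    X[1::2] = (dose == 2).astype(float)
    V[0::2] = called
    V[1::2] = called
    return X, V


def _copy_distance_matrix(X: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Squared allele-difference distances over pairwise-complete loci."""
    Xv = X * V
    cross = Xv @ V.T
    D = cross + cross.T - 2.0 * (Xv @ Xv.T)
    np.fill_diagonal(D, 0.0)
    return D


def _alignment_distance_matrix(aln: HaplotypeAlignment) -> np.ndarray:
    valid = np.isin(aln.sequences, np.frombuffer(b"ACGT", dtype=np.uint8))
    keep = valid.all(axis=0)
    seqs = aln.sequences[:, keep]
    n = aln.n_sequences
    D = np.zeros((n, n))
    for i in range(n):
        D[i] = (seqs != seqs[i]).sum(axis=1)
    return D.astype(float)


_LEVELS_4 = (
    "among groups",
    "among populations within groups",
    "among individuals within populations",
    "within individuals",
)
_LEVELS_3 = ("among groups", "among populations within groups", "within populations")


def amova(
    data: SNPDataset | HaplotypeAlignment,
    scheme: GroupingScheme,
    n_permutations: int = 10000,
    rng: np.random.Generator | None = None,
    permute: tuple[str, ...] | None = None,
) -> AMOVAResult:
    """Hierarchical AMOVA with permutation significance.

    SNP datasets run the four-level decomposition at gene-copy level;
    alignments run the three-level haplotypic decomposition. p-values are
    ``(1 + #{Phi* >= Phi_obs}) / (n_permutations + 1)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    if isinstance(data, SNPDataset):
        return _amova_snp(data, scheme, n_permutations, rng, permute)
    return _amova_haplotypes(data, scheme, n_permutations, rng, permute)


def _result_frame(levels, df, ssd, sig) -> tuple[pd.DataFrame, bool, list[str]]:
    total = np.nansum(sig)
    degenerate = total <= 0
    pct = np.full(len(sig), np.nan) if degenerate else 100.0 * sig / total
    notes = []
    if not degenerate and np.any(sig < 0):
        notes.append("negative variance component estimate retained")
    frame = pd.DataFrame(
        {"level": levels, "df": df.astype(int), "SS": ssd, "variance": sig, "pct_variance": pct}
    )
    return frame, degenerate, notes


def _amova_snp(
    dataset: SNPDataset, scheme: GroupingScheme, n_permutations: int, rng,
    permute: tuple[str, ...] | None = None,
) -> AMOVAResult:
    pops, groups = scheme.labels_for(dataset.individual_ids)
    X, V = _snp_copy_matrix(dataset)
    D = _copy_distance_matrix(X, V)
    n = dataset.n_individuals
    copy_ind = np.repeat(np.arange(n), 2)
    copy_pop = np.repeat(pops, 2)
    copy_group = np.repeat(groups, 2)

    df, sig, notes = _four_level_components(D, copy_ind, copy_pop, copy_group)
    ssd = _four_level_ssd(D, copy_ind, copy_pop, copy_group)
    phi = _phi_from_components(sig)
    frame, degenerate, extra = _result_frame(_LEVELS_4, df, ssd, sig)
    notes += extra

    p_values: dict[str, float] = {}
    if not degenerate and n_permutations > 0:
        p_values = _snp_permutation_pvalues(
            D, pops, groups, phi, n_permutations, rng, permute
        )
    return AMOVAResult(frame, phi, p_values, n_permutations, degenerate, notes)


def _four_level_ssd(D, copy_ind, copy_pop, copy_group) -> np.ndarray:
    C = len(copy_ind)
    ss_total = D.sum() / (2.0 * C)
    ss_g = sum(_set_ss(D, np.flatnonzero(copy_group == g)) for g in np.unique(copy_group))
    ss_p = sum(_set_ss(D, np.flatnonzero(copy_pop == p)) for p in np.unique(copy_pop))
    ss_i = sum(_set_ss(D, np.flatnonzero(copy_ind == i)) for i in np.unique(copy_ind))
    return np.array([ss_total - ss_g, ss_g - ss_p, ss_p - ss_i, ss_i])


def _snp_permutation_pvalues(
    D, pops, groups, phi, n_permutations, rng, permute=None
) -> dict[str, float]:
    def wanted(name: str) -> bool:
        return permute is None or name in permute

    n = len(pops)
    copy_ind = np.repeat(np.arange(n), 2)

    def phi_for(pop_labels: np.ndarray, group_labels: np.ndarray) -> dict[str, float]:
        _, sig, _ = _four_level_components(
            D, copy_ind, np.repeat(pop_labels, 2), np.repeat(group_labels, 2)
        )
        return _phi_from_components(sig)

    p_values: dict[str, float] = {}
    uniq_pops = np.unique(pops)
    group_of_pop = {p: groups[pops == p][0] for p in uniq_pops}

    # Phi_CT: permute whole populations among groups
    if wanted("Phi_CT") and np.isfinite(phi.get("Phi_CT", np.nan)):
        count = 0
        group_slots = np.array([group_of_pop[p] for p in uniq_pops])
        for _ in range(n_permutations):
            perm = rng.permutation(group_slots)
            new_group_of_pop = dict(zip(uniq_pops, perm))
            new_groups = np.array([new_group_of_pop[p] for p in pops])
            if phi_for(pops, new_groups).get("Phi_CT", -np.inf) >= phi["Phi_CT"]:
                count += 1
        p_values["Phi_CT"] = (1 + count) / (n_permutations + 1)

    # Phi_SC: permute individuals among populations within groups
    if wanted("Phi_SC") and np.isfinite(phi.get("Phi_SC", np.nan)):
        count = 0
        for _ in range(n_permutations):
            new_pops = pops.copy()
            for g in np.unique(groups):
                idx = np.flatnonzero(groups == g)
                new_pops[idx] = new_pops[idx][rng.permutation(len(idx))]
            if phi_for(new_pops, groups).get("Phi_SC", -np.inf) >= phi["Phi_SC"]:
                count += 1
        p_values["Phi_SC"] = (1 + count) / (n_permutations + 1)

    # Phi_IS: permute gene copies among individuals within populations
    if wanted("Phi_IS") and np.isfinite(phi.get("Phi_IS", np.nan)):
        count = 0
        copy_pop = np.repeat(pops, 2)
        copy_group = np.repeat(groups, 2)
        base_ind = np.empty(2 * n, dtype=np.int64)
        for _ in range(n_permutations):
            for p in uniq_pops:
                idx = np.flatnonzero(copy_pop == p)
                shuffled = idx[rng.permutation(len(idx))]
                # re-pair consecutive shuffled copies into pseudo-individuals
                base_ind[shuffled] = np.repeat(
                    np.arange(len(idx) // 2), 2
                ) + 10_000 * np.searchsorted(uniq_pops, p)
            _, sig, _ = _four_level_components(D, base_ind, copy_pop, copy_group)
            if _phi_from_components(sig).get("Phi_IS", -np.inf) >= phi["Phi_IS"]:
                count += 1
        p_values["Phi_IS"] = (1 + count) / (n_permutations + 1)
    return p_values


def _amova_haplotypes(
    aln: HaplotypeAlignment, scheme: GroupingScheme, n_permutations: int, rng,
    permute: tuple[str, ...] | None = None,
) -> AMOVAResult:
    pops, groups = scheme.labels_for(aln.ids)
    D = _alignment_distance_matrix(aln)
    df, sig, notes = _three_level_components(D, pops, groups)

    n = len(pops)
    ss_total = D.sum() / (2.0 * n)
    ss_g = sum(_set_ss(D, np.flatnonzero(groups == g)) for g in np.unique(groups))
    ss_p = sum(_set_ss(D, np.flatnonzero(pops == p)) for p in np.unique(pops))
    ssd = np.array([ss_total - ss_g, ss_g - ss_p, ss_p])

    phi = _phi_from_components(sig)
    frame, degenerate, extra = _result_frame(_LEVELS_3, df, ssd, sig)
    notes += extra

    p_values: dict[str, float] = {}
    if not degenerate and n_permutations > 0:
        uniq_pops = np.unique(pops)
        group_of_pop = {p: groups[pops == p][0] for p in uniq_pops}

        def phi_of(pop_labels, group_labels):
            _, s, _ = _three_level_components(D, pop_labels, group_labels)
            return _phi_from_components(s)

        def wanted(name: str) -> bool:
            return permute is None or name in permute

        if wanted("Phi_CT") and np.isfinite(phi.get("Phi_CT", np.nan)):
            count = 0
            slots = np.array([group_of_pop[p] for p in uniq_pops])
            for _ in range(n_permutations):
                perm = rng.permutation(slots)
                new_gop = dict(zip(uniq_pops, perm))
                new_groups = np.array([new_gop[p] for p in pops])
                if phi_of(pops, new_groups).get("Phi_CT", -np.inf) >= phi["Phi_CT"]:
                    count += 1
            p_values["Phi_CT"] = (1 + count) / (n_permutations + 1)
        if wanted("Phi_SC") and np.isfinite(phi.get("Phi_SC", np.nan)):
            count = 0
            for _ in range(n_permutations):
                new_pops = pops.copy()
                for g in np.unique(groups):
                    idx = np.flatnonzero(groups == g)
                    new_pops[idx] = new_pops[idx][rng.permutation(len(idx))]
                if phi_of(new_pops, groups).get("Phi_SC", -np.inf) >= phi["Phi_SC"]:
                    count += 1
            p_values["Phi_SC"] = (1 + count) / (n_permutations + 1)
        if wanted("Phi_ST") and np.isfinite(phi.get("Phi_ST", np.nan)):
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(n)
                if phi_of(pops[perm], groups[perm]).get("Phi_ST", -np.inf) >= phi["Phi_ST"]:
                    count += 1
            p_values["Phi_ST"] = (1 + count) / (n_permutations + 1)
    return AMOVAResult(frame, phi, p_values, n_permutations, degenerate, notes)


def pca_genotypes(
    dataset: SNPDataset, n_components: int = 10, scale: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Genotype PCA with per-locus mean imputation of missing calls.

    Returns ``(coordinates, explained_variance_fractions)``; coordinates
    are centred per component.
    """
    if dataset.n_individuals < 2 or dataset.n_loci < 2:
        raise ValueError("PCA needs >= 2 individuals and >= 2 loci")
    g = dataset.genotypes.astype(float)
    g[g < 0] = np.nan
    col_means = np.nanmean(g, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    idx = np.where(np.isnan(g))
    g[idx] = col_means[idx[1]]
    centered = g - g.mean(axis=0)
    if scale:
        sd = centered.std(axis=0, ddof=0)
        centered = centered / np.where(sd > 0, sd, 1.0)
    if not np.any(centered):
        raise ValueError("zero-variance genotype matrix")
    n_components = min(n_components, *centered.shape)
    U, S, _ = np.linalg.svd(centered, full_matrices=False)
    coords = (U * S)[:, :n_components]
    explained = (S**2 / np.sum(S**2))[:n_components]
    return coords, explained


def weir_cockerham_fst(dataset: SNPDataset, populations: list[str] | None = None) -> float:
    """Multi-locus Weir-Cockerham theta (ratio of averages over loci)."""
    pops = populations if populations is not None else dataset.populations
    if pops is None:
        raise ValueError("population labels required")
    pops = np.asarray(pops)
    uniq = np.unique(pops)
    r = len(uniq)
    if r < 2:
        raise ValueError("need >= 2 populations")
    g = dataset.genotypes
    called = g >= 0
    a_sum = b_sum = c_sum = 0.0
    n_i = np.stack([called[pops == p].sum(axis=0) for p in uniq]).astype(float)
    p_i = np.stack(
        [np.where(n_i[k] > 0, np.where(called[pops == u], g[pops == u], 0).sum(axis=0), 0)
         for k, u in enumerate(uniq)]
    ) / np.maximum(2 * n_i, 1)
    h_i = np.stack(
        [np.where(n_i[k] > 0, ((g[pops == u] == 1) & called[pops == u]).sum(axis=0), 0)
         for k, u in enumerate(uniq)]
    ) / np.maximum(n_i, 1)

    ok = (n_i > 0).all(axis=0)
    n_i, p_i, h_i = n_i[:, ok], p_i[:, ok], h_i[:, ok]
    n_bar = n_i.mean(axis=0)
    n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
    keep = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a_sum, b_sum, c_sum = a[keep].sum(), b[keep].sum(), c[keep].sum()
    denom = a_sum + b_sum + c_sum
    if denom == 0:
        raise ValueError("no polymorphism: FST undefined")
    return float(a_sum / denom)
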