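"""Synthetic-data generators: pseudo-observed ABC datasets, structured
genotypes for AMOVA/PCA calibration, and tiny hand-checkable alignments.

Every generator is a pure function of (configuration, seed); the
:class:`TruthRecord` sidecar stores enough to regenerate a dataset
bit-identically and to score inference results against the known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coalescent_sim import (
    DEFAULT_LOCUS_MUTATION_RATE,
    simulate_snp_dataset,
)
from .datatypes import MISSING, HaplotypeAlignment, SNPDataset
from .demographic_models import TABLE1_POSTERIOR_MEANS, ParameterDraw, build_scenario

__all__ = [
    "TruthRecord",
    "make_pseudo_observed",
    "make_structured_dataset",
    "make_toy_alignment",
    "TOY_ALIGNMENTS",
    "DEFAULT_MISSING_RATE",
]

#: default genotype missingness of the pseudo-observed data: the study kept
#: loci with under 20 % missing calls, so a genome-wide average of half the
#: cap is used as the emulated condition
DEFAULT_MISSING_RATE = 0.1


@dataclass
class TruthRecord:
    """Flat provenance record sufficient to regenerate a dataset."""

    generator: str
    seed: int
    parameters: dict[str, float] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"generator={self.generator}\n")
            fh.write(f"seed={self.seed}\n")
            for key, value in self.parameters.items():
                fh.write(f"param.{key}={value}\n")
            for key, value in self.files.items():
                fh.write(f"file.{key}={value}\n")

    @classmethod
    def from_file(cls, path) -> "TruthRecord":
        generator = ""
        seed = 0
        parameters: dict[str, float] = {}
        files: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                key, _, value = line.rstrip("\n").partition("=")
                if key == "generator":
                    generator = value
                elif key == "seed":
                    seed = int(value)
                elif key.startswith("param."):
                    try:
                        parameters[key[6:]] = int(value)
                    except ValueError:
                        parameters[key[6:]] = float(value)
                elif key.startswith("file."):
                    files[key[5:]] = value
        return cls(generator=generator, seed=seed, parameters=parameters, files=files)


def make_pseudo_observed(
    scenario_id: int = 4,
    params: dict[str, float] | None = None,
    n_individuals: int = 104,
    n_loci: int = 2954,
    missing_rate: float = DEFAULT_MISSING_RATE,
    seed: int = 0,
    locus_mutation_rate: float = DEFAULT_LOCUS_MUTATION_RATE,
    generation_time: float = 1.0,
) -> tuple[SNPDataset, TruthRecord]:
    """Simulate a pseudo-observed SNP dataset with known generating truth.

    Defaults mirror the study design: scenario 4 at the reported posterior
    means, 104 diploid individuals, 2,954 unlinked loci.
    """
    if params is None:
        params = dict(TABLE1_POSTERIOR_MEANS)
        if scenario_id == 5:
            params["t3"] = 1.3e5
            params["N4"] = params["N1"]
        if scenario_id in (1,):
            params = {"N3": params["N3"]}
        elif scenario_id == 2:
            params = {k: params[k] for k in ("N3", "N2", "t1")}
        elif scenario_id == 3:
            params = {k: params[k] for k in ("N3", "N1", "t1")}
    draw = ParameterDraw(scenario_id=scenario_id, values=dict(params),
                         generation_time=generation_time)
    demography = build_scenario(draw)
    rng = np.random.default_rng(seed)
    dataset = simulate_snp_dataset(
        n_individuals,
        n_loci,
        demography,
        locus_mutation_rate=locus_mutation_rate,
        missing_rate=missing_rate,
        rng=rng,
    )
    truth = TruthRecord(
        generator="pseudo_observed",
        seed=seed,
        parameters={
            "scenario_id": scenario_id,
            "n_individuals": n_individuals,
            "n_loci": n_loci,
            "missing_rate": missing_rate,
            "locus_mutation_rate": locus_mutation_rate,
            "generation_time": generation_time,
            **params,
        },
    )
    return dataset, truth


def make_structured_dataset(
    n_pops: int = 3,
    n_per_pop: int = 50,
    n_loci: int = 1000,
    fst: float = 0.1,
    seed: int = 0,
    groups: list[str] | None = None,
) -> tuple[SNPDataset, TruthRecord]:
    """Balding-Nichols structured genotypes with a controllable FST.

    Ancestral allele frequencies are Uniform(0.05, 0.95) per locus (bounds
    avoid quasi-monomorphic loci); each deme draws its frequency from
    Beta(p(1-F)/F, (1-p)(1-F)/F) and genotypes are Binomial(2, deme
    frequency). ``fst = 0`` is the panmictic special case.
    """
    if not 0 <= fst < 1:
        raise ValueError("fst must be in [0, 1)")
    if n_pops < 2:
        raise ValueError("n_pops must be >= 2")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    genotypes = np.empty((n_pops * n_per_pop, n_loci), dtype=np.int8)
    for d in range(n_pops):
        if fst == 0:
            p_deme = p_anc
        else:
            shape = (1.0 - fst) / fst
            p_deme = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
        rows = slice(d * n_per_pop, (d + 1) * n_per_pop)
        genotypes[rows] = rng.binomial(2, p_deme, size=(n_per_pop, n_loci))
    pops = [f"pop{d+1}" for d in range(n_pops) for _ in range(n_per_pop)]
    if groups is None:
        groups = [f"grp{(d % 3) + 1}" for d in range(n_pops) for _ in range(n_per_pop)]
    else:
        if len(groups) != n_pops:
            raise ValueError("groups must list one group per population")
        groups = [groups[d] for d in range(n_pops) for _ in range(n_per_pop)]
    dataset = SNPDataset(genotypes=genotypes, populations=pops, groups=groups)
    truth = TruthRecord(
        generator="structured_balding_nichols",
        seed=seed,
        parameters={"n_pops": n_pops, "n_per_pop": n_per_pop, "n_loci": n_loci, "fst": fst},
    )
    return dataset, truth


def _toy_identical_pair() -> HaplotypeAlignment:
    seq = "ACGTACGTAC" * 10
    return HaplotypeAlignment(sequences=[seq, seq], ids=["a", "b"])


def _toy_two_haplotypes_4seq() -> HaplotypeAlignment:
    """Two haplotypes at frequency 2/2 differing at exactly 1 of 100 sites."""
    base = list("ACGT" * 25)
    alt = base.copy()
    alt[50] = "T" if base[50] != "T" else "A"
    h1 = "".join(base)
    h2 = "".join(alt)
    return HaplotypeAlignment(sequences=[h1, h1, h2, h2], ids=["a", "b", "c", "d"])


def _toy_tajima_n10() -> HaplotypeAlignment:
    """Deterministic 10-sequence alignment with a known site pattern.

    Built from a fixed seed so that S and the pairwise differences are
    reproducible constants; the expected Tajima's D is asserted against an
    exact-arithmetic evaluation of the defining formula in the tests.
    """
    rng = np.random.default_rng(20161107)
    n, L = 10, 60
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    anc = bases[rng.integers(4, size=L)]
    seqs = np.tile(anc, (n, 1))
    for site in rng.choice(L, size=16, replace=False):
        carriers = rng.choice(n, size=rng.integers(1, n), replace=False)
        new = bases[(np.searchsorted(bases, anc[site]) + rng.integers(1, 4)) % 4]
        seqs[carriers, site] = new
    return HaplotypeAlignment(sequences=seqs)


def _toy_six_haplotypes_two_groups() -> HaplotypeAlignment:
    """Six sequences, all variation between two groups of three."""
    h1 = "AAAA" + "ACGT" * 9
    h2 = "TTTT" + "ACGT" * 9
    return HaplotypeAlignment(
        sequences=[h1, h1, h1, h2, h2, h2],
        ids=[f"s{i}" for i in range(6)],
        populations=["p1", "p1", "p2", "p3", "p3", "p4"],
    )


TOY_ALIGNMENTS = {
    "identical_pair": _toy_identical_pair,
    "two_haplotypes_4seq": _toy_two_haplotypes_4seq,
    "tajima_n10": _toy_tajima_n10,
    "six_haplotypes_two_groups": _toy_six_haplotypes_two_groups,
}


def make_toy_alignment(name: str) -> HaplotypeAlignment:
    """Deterministic, hand-checkable fixture alignments by registry name."""
    try:
        factory = TOY_ALIGNMENTS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(TOY_ALIGNMENTS)}"
        ) from None
    return factory()
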