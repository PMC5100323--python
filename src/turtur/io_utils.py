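"""Readers and writers for the standard formats, plus run configuration.

Formats: FASTA alignments (via Biopython), a minimal VCF v4.2 subset for
unphased diploid genotypes (read via pysam, written directly), a delimited
0/1/2 genotype matrix, and the sample -> population -> group popmap TSV.
VCF coordinates are 1-based per the standard; internal locus indexing is
0-based, with the conversion confined to this module.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO

from .datatypes import MISSING, HaplotypeAlignment, SNPDataset

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_genotypes",
    "write_vcf",
    "write_matrix012",
    "RunConfig",
    "parse_number",
    "ne_nc_ratio",
]

logger = logging.getLogger(__name__)


def parse_number(text: str) -> float:
    """Parse a number, tolerating Unicode minus signs and thin separators."""
    cleaned = (
        text.strip()
        .replace("−", "-")  # Unicode minus
        .replace("–", "-")
        .replace(",", "")
        .replace(" ", "")
        .replace(" ", "")
    )
    return float(cleaned)


def ne_nc_ratio(ne: float, nc: float, decimals: int = 3) -> float:
    """Effective-to-census size ratio, rounded half-even at ``decimals``."""
    if ne <= 0 or nc <= 0:
        raise ValueError("Ne and Nc must be positive")
    from decimal import ROUND_HALF_EVEN, Decimal

    quantum = Decimal(1).scaleb(-decimals)
    ratio = Decimal(str(ne)) / Decimal(str(nc))
    return float(ratio.quantize(quantum, rounding=ROUND_HALF_EVEN))


def read_fasta(path, pad: bool = False) -> HaplotypeAlignment:
    """Read an aligned FASTA into a :class:`HaplotypeAlignment`.

    Sequences are uppercased; ragged lengths are rejected unless ``pad`` is
    set (right-padding with ``-``). Duplicate identifiers are an error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence identifiers: {dupes}")
    seqs = [str(r.seq).upper() for r in records]
    if any(not s for s in seqs):
        raise ValueError("empty sequence in FASTA")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        if not pad:
            raise ValueError("sequences have unequal lengths (pass pad=True to pad)")
        L = max(lengths)
        seqs = [s.ljust(L, "-") for s in seqs]
    return HaplotypeAlignment(sequences=seqs, ids=ids)


def write_fasta(aln: HaplotypeAlignment, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(aln.ids, aln.sequence_strings()):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_genotypes(path, format: str = "vcf") -> SNPDataset:
    """Read genotypes from VCF or a 0/1/2 matrix.

    VCF: only biallelic rows are kept (others are skipped and counted in
    the log); phased and unphased GT fields are both accepted; ``./.``
    becomes missing. matrix012: header row of locus ids, first column
    sample ids, entries in {0, 1, 2, NA}.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix012":
        return _read_matrix012(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> SNPDataset:
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    rows = []
    locus_ids = []
    n_skipped = 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            n_skipped += 1
            continue
        row = np.empty(len(samples), dtype=np.int8)
        for i, sample in enumerate(samples):
            gt = rec.samples[sample]["GT"]
            if gt is None or any(a is None for a in gt):
                row[i] = MISSING
            else:
                row[i] = sum(gt)
        rows.append(row)
        locus_ids.append(rec.id if rec.id else f"{rec.chrom}:{rec.pos}")
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic VCF records", n_skipped)
    if not rows:
        raise ValueError("no biallelic records in VCF")
    dataset = SNPDataset(genotypes=np.stack(rows).T, individual_ids=samples, locus_ids=locus_ids)
    dataset.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return dataset


def write_vcf(dataset: SNPDataset, path) -> None:
    """Write a minimal VCF v4.2 with unphased GT calls on one contig."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=turtur\n")
        fh.write(f"##contig=<ID=1,length={dataset.n_loci + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.individual_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, locus in enumerate(dataset.locus_ids):
            calls = "\t".join(gt_map[int(g)] for g in dataset.genotypes[:, j])
            fh.write(f"1\t{j + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def _read_matrix012(path) -> SNPDataset:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.empty:
        raise ValueError("empty genotype matrix")
    values = df.to_numpy()
    genotypes = np.empty(values.shape, dtype=np.int8)
    allowed = {"0": 0, "1": 1, "2": 2, "NA": MISSING}
    for code, value in allowed.items():
        genotypes[values == code] = value
    bad = ~np.isin(values, list(allowed))
    if bad.any():
        raise ValueError(f"invalid matrix012 entries, e.g. {values[bad][0]!r}")
    return SNPDataset(
        genotypes=genotypes,
        individual_ids=[str(s) for s in df.index],
        locus_ids=[str(c) for c in df.columns],
    )


def write_matrix012(dataset: SNPDataset, path) -> None:
    as_text = np.where(dataset.genotypes == MISSING, "NA", dataset.genotypes.astype(str))
    df = pd.DataFrame(as_text, index=dataset.individual_ids, columns=dataset.locus_ids)
    df.to_csv(path, sep="\t")


@dataclass
class RunConfig:
    """Serializable run configuration echoed into every output header."""

    seed: int = 0
    generation_time: float = 1.0
    locus_mutation_rate: float = 2.5e-7
    missing_rate: float = 0.1
    mtdna_clock_rate: float = 0.021
    n_sims_per_scenario: int = 10_000
    tolerance_direct: float = 0.001
    tolerance_logistic: float = 0.01
    n_permutations: int = 10_000
    deletion_mode: str = "complete"
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        return cls(**kwargs)

    def header_lines(self) -> list[str]:
        d = dataclasses.asdict(self)
        d.pop("extra")
        lines = [f"# {key}: {value}" for key, value in d.items()]
        lines += [f"# {key}: {value}" for key, value in self.extra.items()]
        return lines


def write_report(path, lines: list[str], config: RunConfig | None = None) -> None:
    """Write a flat text report with an optional config echo header."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write("\n".join(config.header_lines()) + "\n")
        fh.write("\n".join(lines) + "\n")
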