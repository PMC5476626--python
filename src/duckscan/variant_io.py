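"""Containers and readers/writers for variants, scaffolds and gene annotation.

All coordinates are 0-based half-open internally.  VCF input and output use
1-based positions per the VCFv4.2 standard; BED is 0-based half-open; GFF3 is
1-based inclusive.  Genotypes are stored as an (n_sites, n_samples, 2) int8
array with -1 marking a missing allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["gene_id", "scaffold", "start", "end", "strand"]

#: Scaffolds at or below this length are discarded before windowed statistics
#: (strictly "larger than" is retained).
DEFAULT_MIN_SCAFFOLD_LENGTH = 60_000


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be parsed."""


class ConfigurationError(ValueError):
    """Raised for inconsistent sample/population configuration."""


@dataclass
class VariantTable:
    """Biallelic SNP genotypes for a two-population diploid cohort.

    Parameters
    ----------
    scaffold, pos
        Per-site scaffold id and 0-based position; positions must be strictly
        increasing within a scaffold.
    ref, alt
        Single-base REF/ALT alleles.
    genotypes
        ``(n_sites, n_samples, 2)`` int8 array; allele 0 = REF, 1 = ALT,
        -1 = missing.
    samples
        Sample ids, column order of ``genotypes``.
    populations
        Mapping sample id -> population label.
    """

    scaffold: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    samples: list[str]
    populations: dict[str, str]

    def __post_init__(self) -> None:
        self.scaffold = np.asarray(self.scaffold, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (self.pos.size, len(self.samples), 2):
            raise ValueError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{self.pos.size} sites x {len(self.samples)} samples x 2"
            )
        missing = [s for s in self.samples if s not in self.populations]
        if missing:
            raise ConfigurationError(f"samples without a population label: {missing}")
        for scaf in pd.unique(self.scaffold):
            p = self.pos[self.scaffold == scaf]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {scaf}")

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def population_samples(self, population: str) -> list[str]:
        out = [s for s in self.samples if self.populations[s] == population]
        if not out:
            raise ConfigurationError(f"no samples in population {population!r}")
        return out

    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.populations[s], None)
        return list(seen)

    def equals(self, other: "VariantTable") -> bool:
        return (
            self.samples == other.samples
            and self.populations == other.populations
            and np.array_equal(self.scaffold, other.scaffold)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class AlleleCountTable:
    """Per-site ALT-allele counts for one population.

    ``c_alt``/``n_called`` are allele counts (``n_called`` excludes missing
    alleles); ``n_het``/``n_ind`` count heterozygous and fully-called
    individuals, needed by the Weir-Cockerham variance components.
    """

    population: str
    scaffold: np.ndarray
    pos: np.ndarray
    c_alt: np.ndarray
    n_called: np.ndarray
    n_het: np.ndarray
    n_ind: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.c_alt > self.n_called) or np.any(self.c_alt < 0):
            raise ValueError("require 0 <= c_alt <= n_called at every site")

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def uninformative(self) -> np.ndarray:
        """Sites with no called alleles in this population."""
        return self.n_called == 0


def allele_counts(vt: VariantTable, population: str | None = None) -> AlleleCountTable:
    """Count ALT alleles per site over one population (or all samples).

    Missing alleles are excluded from ``n_called``; an individual counts as
    heterozygous only when both of its alleles are called.
    """
    if population is None:
        idx = np.arange(vt.n_samples)
        label = "all"
    else:
        names = vt.population_samples(population)
        idx = np.array([vt.samples.index(s) for s in names])
        label = population
    g = vt.genotypes[:, idx, :]
    called = g >= 0
    both_called = called.all(axis=2)
    return AlleleCountTable(
        population=label,
        scaffold=vt.scaffold,
        pos=vt.pos,
        c_alt=(g == 1).sum(axis=(1, 2)),
        n_called=called.sum(axis=(1, 2)),
        n_het=((g[:, :, 0] != g[:, :, 1]) & both_called).sum(axis=1),
        n_ind=both_called.sum(axis=1),
    )


@dataclass
class ScaffoldIndex:
    """Scaffold id -> length (bp), with a retained flag per scaffold."""

    lengths: dict[str, int]
    retained: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.lengths.values()):
            raise ValueError("scaffold lengths must be positive")
        if not self.retained:
            self.retained = {s: True for s in self.lengths}

    def retained_ids(self) -> list[str]:
        return [s for s in self.lengths if self.retained[s]]


def filter_scaffolds(
    idx: ScaffoldIndex, min_length: int = DEFAULT_MIN_SCAFFOLD_LENGTH
) -> ScaffoldIndex:
    """Retain scaffolds strictly longer than ``min_length`` bp.

    The comparison is strict ("larger than"), so a scaffold of exactly
    ``min_length`` is dropped.  Idempotent: re-filtering never re-adds a
    scaffold.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    retained = {
        s: idx.retained[s] and (length > min_length) for s, length in idx.lengths.items()
    }
    return ScaffoldIndex(lengths=dict(idx.lengths), retained=retained)


def read_fai(path) -> ScaffoldIndex:
    """Build a ScaffoldIndex from a FASTA index (.fai); only name/length used."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["name", "length"])
    return ScaffoldIndex(lengths=dict(zip(df["name"].astype(str), df["length"].astype(int))))


def write_fai(lengths: dict[str, int], path) -> None:
    offset = 0
    with open(path, "w") as fh:
        for name, length in lengths.items():
            fh.write(f"{name}\t{length}\t{offset}\t80\t81\n")
            offset += length + length // 80 + len(name) + 3


def read_sample_groups(path) -> dict[str, str]:
    """Two-column TSV (sample, population) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    return dict(zip(df["sample"], df["population"]))


def write_sample_groups(groups: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, pop in groups.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path, sample_groups: dict[str, str]) -> VariantTable:
    """Read biallelic SNPs from a VCF into a VariantTable.

    Indels and multi-allelic records are dropped (counts logged).  Every VCF
    sample must appear in ``sample_groups``.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in sample_groups]
    if unknown:
        raise ConfigurationError(f"VCF samples missing from the groups file: {unknown}")

    scaffolds: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    gts: list[np.ndarray] = []
    n_indel = n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if not var.is_snp:
            n_indel += 1
            continue
        g = np.array([row[:2] for row in var.genotypes], dtype=np.int8)
        scaffolds.append(var.CHROM)
        positions.append(var.start)  # cyvcf2 start is already 0-based
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gts.append(g)
    log.info(
        "read %d SNPs from %s (dropped %d non-SNP, %d multi-allelic records)",
        len(positions), path, n_indel, n_multi,
    )
    geno = (
        np.stack(gts) if gts else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    return VariantTable(
        scaffold=np.array(scaffolds, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=geno,
        samples=samples,
        populations={s: sample_groups[s] for s in samples},
    )


def write_vcf(vt: VariantTable, path, scaffold_lengths: dict[str, int] | None = None) -> None:
    """Write a VariantTable as an uncompressed VCFv4.2 with GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=duckscan\n")
        if scaffold_lengths:
            for name, length in scaffold_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(vt.samples) + "\n")
        for i in range(vt.n_sites):
            gt_strs = [
                "/".join("." if a < 0 else str(int(a)) for a in pair)
                for pair in vt.genotypes[i]
            ]
            fh.write(
                f"{vt.scaffold[i]}\t{vt.pos[i] + 1}\t.\t{vt.ref[i]}\t{vt.alt[i]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gt_strs) + "\n"
            )


# ---------------------------------------------------------------------------
# Gene annotation (BED6 / GFF3)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns {missing}")
    if (ann["start"] >= ann["end"]).any():
        raise ValueError("annotation requires start < end")
    return ann[ANNOTATION_COLUMNS].reset_index(drop=True)


def write_bed(ann: pd.DataFrame, path) -> None:
    ann = validate_annotation(ann)
    with open(path, "w") as fh:
        for row in ann.itertuples(index=False):
            fh.write(
                f"{row.scaffold}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n"
            )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["scaffold", "start", "end", "gene_id", "score", "strand"],
        dtype={"scaffold": str, "gene_id": str, "strand": str},
    )
    return validate_annotation(df)


def write_gff3(ann: pd.DataFrame, path) -> None:
    ann = validate_annotation(ann)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in ann.itertuples(index=False):
            fh.write(
                f"{row.scaffold}\tduckscan\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append(
                {
                    "gene_id": attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}"),
                    "scaffold": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                }
            )
    return validate_annotation(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS))
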