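"""Generate the synthetic two-breed cohort used by the downstream analyses.

Writes, under results/sim/: a VCF of ~40k biallelic SNPs for 9 + 9 diploids
on ten 4.02-Mb scaffolds with ten planted 40-kb sweep windows, the scaffold
index, sample-to-breed map, a BED of 2,000 genes, an NB count matrix for the
four muscle groups (BD3/CD3/BD6/CD6, 2 replicates each, 10% planted DE at
|log2FC| = 2), and the planted-truth JSON files that later steps score
against.
"""

from pathlib import Path

from duckscan.expression import write_counts_tsv
from duckscan.synthetic_data import (
    SimExprConfig, SimGenotypeConfig, simulate_annotation, simulate_expression,
    simulate_two_pop_genotypes,
)
from duckscan.variant_io import (
    write_bed, write_fai, write_sample_groups, write_vcf,
)

SEED = 1
OUT = Path("results/sim")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gcfg = SimGenotypeConfig(seed=SEED)
    vt, sweep_truth = simulate_two_pop_genotypes(gcfg)
    ann = simulate_annotation(gcfg.scaffold_lengths, 2_000, seed=SEED + 1)
    ecfg = SimExprConfig(
        seed=SEED + 2,
        gene_ids=tuple(ann["gene_id"]),
        gene_lengths=tuple(ann["end"] - ann["start"]),
    )
    cm, de_truth = simulate_expression(ecfg)

    write_vcf(vt, OUT / "cohort.vcf", gcfg.scaffold_lengths)
    write_fai(gcfg.scaffold_lengths, OUT / "genome.fai")
    write_sample_groups(vt.populations, OUT / "groups.tsv")
    write_bed(ann, OUT / "genes.bed")
    write_counts_tsv(cm, OUT / "counts.tsv")
    write_sample_groups(cm.groups, OUT / "expr_groups.tsv")
    sweep_truth.to_json(OUT / "sweep_truth.json")
    de_truth.to_json(OUT / "de_truth.json")

    print(f"cohort: {vt.n_sites} SNPs, {vt.n_samples} ducks "
          f"({len(gcfg.sweep_windows)} planted sweep windows)")
    print(f"annotation: {len(ann)} genes on {ann['scaffold'].nunique()} scaffolds")
    print(f"counts: {cm.counts.shape[0]} genes x {cm.counts.shape[1]} libraries, "
          f"{len(de_truth.designated)} planted DE genes")
    print(f"outputs under {OUT}/")


if __name__ == "__main__":
    main()
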