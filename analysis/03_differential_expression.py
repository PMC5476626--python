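"""Differential expression across the four group contrasts.

Reads the count matrix written by 01_simulate_cohort.py, applies the
RPKM >= 0.1 expressed filter per group, runs the NB Wald test on the four
contrasts (BD3vCD3, BD6vCD6, BD3vBD6, CD3vCD6), applies the DEG rule
(padj < 0.05 and FC > 2 or < 0.5), scores recall against the planted truth,
and writes per-contrast tables under results/de/.
"""

from pathlib import Path

from duckscan.expression import (
    call_deg_sets, expressed_filter, read_counts_tsv, rpkm, run_all_contrasts,
)
from duckscan.synthetic_data import DETruth
from duckscan.variant_io import read_sample_groups

SIM = Path("results/sim")
OUT = Path("results/de")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cm = read_counts_tsv(SIM / "counts.tsv", read_sample_groups(SIM / "expr_groups.tsv"))
    flags = expressed_filter(rpkm(cm), cm.groups)
    print(f"{len(cm.counts)} genes; {int(flags.all(axis=1).sum())} expressed in "
          f"all four groups (group-mean RPKM >= 0.1)")

    results = run_all_contrasts(cm)
    truth = DETruth.from_json(SIM / "de_truth.json")
    summary = call_deg_sets(results)
    for name, res in results.items():
        res.table.to_csv(OUT / f"deg_{name}.tsv", sep="\t", index_label="gene_id",
                         float_format="%.6g")
        called = set(res.table.index[res.table["deg"]])
        true_set = set(truth.affected[name])
        tp = len(called & true_set)
        c = summary["counts"][name]
        print(f"{name}: {c['total']} DEGs ({c['up']} up, {c['down']} down); "
              f"recall {tp}/{len(true_set)}, "
              f"false discoveries {len(called - true_set)}/{len(called)}")
    print(f"within-breed overlap (DE across age in both breeds): "
          f"{len(summary['within_breed_overlap'])} genes")


if __name__ == "__main__":
    main()
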