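"""Intersect the PSG list with the DEG sets into the candidate-gene matrix.

Reads results/scan/psgs.tsv and results/de/deg_*.tsv, keeps genes that are
both positively selected and differentially expressed in at least one
contrast, and classifies each candidate from its contrast pattern
(between-breed at 3 wk -> muscle growth; between-breed at 6 wk -> lipid
deposition; within-breed only -> breast growth).  Writes
results/integration/candidates.tsv in the check-mark table layout.
"""

from pathlib import Path

import pandas as pd

from duckscan.integration import candidate_table, classify_candidates, combine_psg_deg

SCAN = Path("results/scan")
DE = Path("results/de")
OUT = Path("results/integration")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    psgs = pd.read_csv(SCAN / "psgs.tsv", sep="\t")["gene_id"].astype(str)
    deg_sets = {}
    for path in sorted(DE.glob("deg_*.tsv")):
        name = path.stem.removeprefix("deg_")
        tab = pd.read_csv(path, sep="\t", index_col=0)
        hit = tab[tab["deg"]]
        deg_sets[name] = dict(zip(hit.index.astype(str), hit["direction"]))

    records = classify_candidates(combine_psg_deg(psgs, deg_sets))
    table = candidate_table(records)
    table.to_csv(OUT / "candidates.tsv", sep="\t", index=False)

    print(f"{len(psgs)} PSGs x DEG sets "
          f"{ {k: len(v) for k, v in deg_sets.items()} }")
    print(f"{len(records)} candidate genes (PSG and DEG in >= 1 contrast)")
    for label in ("muscle-growth", "lipid-deposition", "breast-growth"):
        n = sum(1 for r in records if label in r.labels)
        print(f"  {label}: {n}")
    print(f"table -> {OUT / 'candidates.tsv'}")


if __name__ == "__main__":
    main()
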