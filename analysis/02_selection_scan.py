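"""Windowed Z(Fst) + Tajima's D scan of the simulated cohort.

Reads the cohort written by 01_simulate_cohort.py, computes 40-kb/20-kb
sliding-window statistics per breed, Z-transforms window Fst genome-wide,
calls windows in the joint (high Z(Fst), low Tajima's D) 5% tails, merges
them into regions and maps them onto genes.  Scores recall against the
planted sweep windows and writes the window table, region BED and PSG list
under results/scan/.
"""

from pathlib import Path

import numpy as np

from duckscan.popgen import window_stats
from duckscan.sweep_scan import call_selected_windows, map_windows_to_genes, zscore_fst
from duckscan.synthetic_data import SweepTruth
from duckscan.variant_io import (
    filter_scaffolds, read_bed, read_fai, read_sample_groups, read_vcf,
)

SIM = Path("results/sim")
OUT = Path("results/scan")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    vt = read_vcf(SIM / "cohort.vcf", read_sample_groups(SIM / "groups.tsv"))
    idx = filter_scaffolds(read_fai(SIM / "genome.fai"))
    stats = zscore_fst(window_stats(vt, "BD", "CD", idx))
    res = call_selected_windows(stats, level=0.05, d_population_rule="either")
    psgs = map_windows_to_genes(res.calls, read_bed(SIM / "genes.bed"))

    res.windows.to_csv(OUT / "window_stats.tsv", sep="\t", index=False,
                       float_format="%.6g")
    with open(OUT / "selected_regions.bed", "w") as fh:
        for c in res.calls:
            fh.write(f"{c.scaffold}\t{c.start}\t{c.end}\n")
    psgs.to_csv(OUT / "psgs.tsv", sep="\t", index=False, float_format="%.6g")

    truth = SweepTruth.from_json(SIM / "sweep_truth.json")
    win = res.windows
    flagged = win["selected"].to_numpy()
    recovered = 0
    for scaf, s, e in truth.windows:
        m = ((win["scaffold"] == scaf) & (win["start"] < e) & (win["end"] > s)).to_numpy()
        recovered += int((flagged & m).any())

    print(f"{len(win)} windows on {win['scaffold'].nunique()} scaffolds; "
          f"mean Fst {win['fst'].mean():.4f}")
    print(f"Z(Fst) 5% threshold {res.thresholds.z_hi[0.05]:.4f}, "
          f"1% threshold {res.thresholds.z_hi[0.01]:.4f}")
    print(f"Tajima's D 5% thresholds {res.thresholds.d_lo[0.05]}")
    print(f"{int(flagged.sum())} selected windows -> {len(res.calls)} regions "
          f"-> {len(psgs)} PSGs")
    print(f"recovered {recovered}/{len(truth.windows)} planted sweep windows")


if __name__ == "__main__":
    main()
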