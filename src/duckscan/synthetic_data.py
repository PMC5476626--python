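"""Synthetic two-breed cohorts with planted truth.

Three generators make the whole pipeline verifiable without any download:

* ``simulate_two_pop_genotypes`` — biallelic SNPs for two diploid populations
  under the Balding-Nichols model: each site draws an ancestral frequency
  p ~ U(0.05, 0.95) and per-population frequencies from
  Beta(p(1-F)/F, (1-p)(1-F)/F), so F is the expected Fst.  Designated sweep
  windows use an elevated F and, with probability ``sweep_fix_prob``, push the
  target population's frequency to the nearer of 0/1 — jointly raising Fst
  and depressing diversity and Tajima's D there, which is the signature the
  scan must recover.
* ``simulate_annotation`` — non-overlapping gene intervals with stable ids.
* ``simulate_expression`` — NB-distributed counts for four groups (two breeds
  x two ages, 2 replicates each) with a designated fraction of DE genes at a
  stated log2 fold change.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import GROUPS, CONTRASTS, CountMatrix, contrast_name
from .variant_io import ANNOTATION_COLUMNS, VariantTable, validate_annotation


class CoordinateError(ValueError):
    """A planted window or gene does not fit its scaffold."""


class PlacementError(RuntimeError):
    """Could not place the requested number of non-overlapping genes."""


def _default_scaffolds() -> dict[str, int]:
    # 10 scaffolds x 4.02 Mb -> 200 windows each at 40 kb / 20 kb = 2,000 windows
    return {f"scaffold_{i}": 4_020_000 for i in range(1, 11)}


def _default_sweeps() -> tuple[tuple[str, int, int], ...]:
    return tuple((f"scaffold_{i}", 2_000_000, 2_040_000) for i in range(1, 11))


@dataclass
class SimGenotypeConfig:
    """Two-population genotype simulation settings.

    Defaults emulate the study design at desk scale: 9 diploids per breed,
    a genome-wide baseline differentiation of F = 0.05, and ten planted
    40-kb sweep windows (one per scaffold) at F = 0.4 with a 0.8 per-site
    fixation push in the target breed.
    """

    n_per_pop: int = 9
    scaffold_lengths: dict[str, int] = field(default_factory=_default_scaffolds)
    snp_density: float = 1e-3
    baseline_fst: float = 0.05
    sweep_windows: tuple[tuple[str, int, int], ...] = field(default_factory=_default_sweeps)
    sweep_fst: float = 0.4
    sweep_fix_prob: float = 0.8
    target_pop: str = "BD"
    pop_labels: tuple[str, str] = ("BD", "CD")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_fst < self.sweep_fst < 1.0:
            raise ValueError("require 0 < baseline_fst < sweep_fst < 1")
        if not 0.0 <= self.sweep_fix_prob <= 1.0:
            raise ValueError("sweep_fix_prob must be in [0, 1]")
        if self.target_pop not in self.pop_labels:
            raise ValueError("target_pop must be one of pop_labels")
        for scaf, start, end in self.sweep_windows:
            if scaf not in self.scaffold_lengths:
                raise CoordinateError(f"sweep window on unknown scaffold {scaf!r}")
            if not (0 <= start < end <= self.scaffold_lengths[scaf]):
                raise CoordinateError(
                    f"sweep window [{start}, {end}) outside {scaf} "
                    f"(length {self.scaffold_lengths[scaf]})"
                )


@dataclass
class SweepTruth:
    """Planted sweep intervals and per-site sweep-regime flags."""

    windows: list[tuple[str, int, int]]
    site_flags: np.ndarray  # bool per retained site

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "windows": [list(w) for w in self.windows],
                    "site_flags": self.site_flags.astype(int).tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "SweepTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            windows=[tuple(w) for w in d["windows"]],
            site_flags=np.array(d["site_flags"], dtype=bool),
        )


def simulate_two_pop_genotypes(config: SimGenotypeConfig) -> tuple[VariantTable, SweepTruth]:
    """Draw genotypes for two populations under the Balding-Nichols model.

    Sites monomorphic across the combined sample are dropped (a variant
    caller would not emit them), so the returned truth flags refer to the
    retained sites only.
    """
    rng = np.random.default_rng(config.seed)
    pop1, pop2 = config.pop_labels
    samples = [f"{p}_{i + 1}" for p in config.pop_labels for i in range(config.n_per_pop)]
    populations = {s: s.rsplit("_", 1)[0] for s in samples}

    scaffolds_out, pos_out, geno_out, flags_out = [], [], [], []
    bases = np.array(list("ACGT"))
    for scaf, length in config.scaffold_lengths.items():
        n_sites = int(rng.poisson(config.snp_density * length))
        if n_sites == 0:
            continue
        pos = np.sort(rng.choice(length, size=min(n_sites, length), replace=False))
        n_sites = pos.size
        in_sweep = np.zeros(n_sites, dtype=bool)
        for wscaf, start, end in config.sweep_windows:
            if wscaf == scaf:
                in_sweep |= (pos >= start) & (pos < end)

        p = rng.uniform(0.05, 0.95, n_sites)
        F = np.where(in_sweep, config.sweep_fst, config.baseline_fst)
        a, b = p * (1 - F) / F, (1 - p) * (1 - F) / F
        freqs = {pop1: rng.beta(a, b), pop2: rng.beta(a, b)}
        push = in_sweep & (rng.random(n_sites) < config.sweep_fix_prob)
        tf = freqs[config.target_pop]
        tf[push] = np.round(tf[push])  # nearer of 0/1

        geno = np.concatenate(
            [
                (
                    rng.random((n_sites, config.n_per_pop, 2))
                    < freqs[pop][:, None, None]
                ).astype(np.int8)
                for pop in config.pop_labels
            ],
            axis=1,
        )
        alt_total = geno.sum(axis=(1, 2))
        poly = (alt_total > 0) & (alt_total < 2 * geno.shape[1])
        scaffolds_out.append(np.full(poly.sum(), scaf, dtype=object))
        pos_out.append(pos[poly])
        geno_out.append(geno[poly])
        flags_out.append(in_sweep[poly])

    n_total = sum(a.size for a in pos_out)
    ref_alt = rng.integers(0, 4, size=(n_total, 1)) + np.array([[0, 1]])
    vt = VariantTable(
        scaffold=np.concatenate(scaffolds_out) if scaffolds_out else np.empty(0, object),
        pos=np.concatenate(pos_out) if pos_out else np.empty(0, np.int64),
        ref=bases[ref_alt[:, 0] % 4],
        alt=bases[ref_alt[:, 1] % 4],
        genotypes=(
            np.concatenate(geno_out)
            if geno_out
            else np.empty((0, len(samples), 2), np.int8)
        ),
        samples=samples,
        populations=populations,
    )
    truth = SweepTruth(
        windows=[tuple(w) for w in config.sweep_windows],
        site_flags=np.concatenate(flags_out) if flags_out else np.empty(0, bool),
    )
    return vt, truth


def simulate_annotation(
    scaffold_lengths: dict[str, int],
    n_genes: int,
    seed: int = 0,
    length_range: tuple[int, int] = (2_000, 10_000),
    max_tries: int = 200,
) -> pd.DataFrame:
    """Place non-overlapping gene intervals uniformly across scaffolds.

    Genes are allocated to scaffolds in proportion to length and placed by
    rejection sampling; a scaffold that cannot accommodate its share raises
    ``PlacementError``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    names = list(scaffold_lengths)
    lengths = np.array([scaffold_lengths[s] for s in names], dtype=float)
    share = np.floor(n_genes * lengths / lengths.sum()).astype(int)
    for i in range(n_genes - share.sum()):  # distribute the remainder
        share[i % len(names)] += 1

    rows = []
    gene_no = 0
    for scaf, quota in zip(names, share):
        L = scaffold_lengths[scaf]
        starts: list[int] = []
        ends: list[int] = []
        for _ in range(quota):
            for attempt in range(max_tries):
                glen = int(rng.integers(length_range[0], length_range[1] + 1))
                if glen >= L:
                    continue
                start = int(rng.integers(0, L - glen))
                i = bisect.bisect_right(starts, start)
                if (i > 0 and ends[i - 1] > start) or (
                    i < len(starts) and starts[i] < start + glen
                ):
                    continue
                starts.insert(i, start)
                ends.insert(i, start + glen)
                gene_no += 1
                rows.append(
                    {
                        "gene_id": f"gene{gene_no:05d}",
                        "scaffold": scaf,
                        "start": start,
                        "end": start + glen,
                        "strand": "+" if rng.random() < 0.5 else "-",
                    }
                )
                break
            else:
                raise PlacementError(
                    f"could not place {quota} non-overlapping genes on {scaf}"
                )
    ann = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return validate_annotation(ann.sort_values(["scaffold", "start"]))


@dataclass
class SimExprConfig:
    """NB count-matrix simulation settings.

    Defaults mirror the study's transcriptome arm at desk scale: four groups
    (two breeds x two ages) with 2 replicates each, 2,000 genes, 10% DE at
    |log2FC| = 2 and NB dispersion 0.05.  ``mean_count_log_range`` is the
    log10 range of baseline mean counts.
    """

    n_genes: int = 2_000
    replicates_per_group: int = 2
    groups: tuple[str, ...] = GROUPS
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    mean_count_log_range: tuple[float, float] = (0.5, 3.0)
    gene_length_range: tuple[int, int] = (500, 5_000)
    seed: int = 0
    gene_ids: tuple[str, ...] | None = None
    gene_lengths: tuple[int, ...] | None = None
    de_contrasts: tuple[tuple[str, str], ...] = CONTRASTS

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.gene_ids is not None and len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids length must equal n_genes")


@dataclass
class DETruth:
    """Planted differential expression: designated shifts and affected contrasts."""

    designated: dict[str, tuple[str, int]]       # gene -> (contrast name, sign)
    affected: dict[str, dict[str, float]]        # contrast name -> {gene: true log2 ratio}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"designated": self.designated, "affected": self.affected}, fh)

    @classmethod
    def from_json(cls, path) -> "DETruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            designated={g: tuple(v) for g, v in d["designated"].items()},
            affected=d["affected"],
        )


def simulate_expression(config: SimExprConfig) -> tuple[CountMatrix, DETruth]:
    """Draw an NB count matrix with planted DE genes.

    Each DE gene is assigned one contrast (round-robin over
    ``de_contrasts``) and a random sign; the shift multiplies the first
    group of that contrast by ``2**(sign*de_log2fc)``.  Because a shifted
    group also takes part in other contrasts, the truth records, for every
    standard contrast, all genes whose group means actually differ, with the
    true log2 ratio.
    """
    rng = np.random.default_rng(config.seed)
    ids = (
        list(config.gene_ids)
        if config.gene_ids is not None
        else [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    )
    lengths = (
        np.asarray(config.gene_lengths)
        if config.gene_lengths is not None
        else rng.integers(*config.gene_length_range, size=config.n_genes)
    )
    lo, hi = config.mean_count_log_range
    base = 10.0 ** rng.uniform(lo, hi, config.n_genes)
    means = pd.DataFrame(
        np.tile(base[:, None], (1, len(config.groups))), index=ids, columns=config.groups
    )

    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    designated: dict[str, tuple[str, int]] = {}
    for k, gi in enumerate(de_idx):
        ga, gb = config.de_contrasts[k % len(config.de_contrasts)]
        sign = 1 if rng.random() < 0.5 else -1
        means.loc[ids[gi], ga] *= 2.0 ** (sign * config.de_log2fc)
        designated[ids[gi]] = (contrast_name((ga, gb)), sign)

    affected: dict[str, dict[str, float]] = {}
    for ga, gb in CONTRASTS:
        if ga in means.columns and gb in means.columns:
            ratio = np.log2(means[gb] / means[ga])
            hit = ratio[ratio != 0.0]
            affected[contrast_name((ga, gb))] = dict(hit)

    samples = [
        f"{g}_{r + 1}" for g in config.groups for r in range(config.replicates_per_group)
    ]
    groups_map = {s: s.rsplit("_", 1)[0] for s in samples}
    alpha = config.nb_dispersion
    cols = {}
    for s in samples:
        mu = means[groups_map[s]].to_numpy()
        if alpha < 1e-10:
            cols[s] = rng.poisson(mu)
        else:
            n_param = 1.0 / alpha
            p_param = n_param / (n_param + mu)
            cols[s] = rng.negative_binomial(n_param, p_param)
    counts = pd.DataFrame(cols, index=ids)
    cm = CountMatrix(
        counts=counts, lengths=pd.Series(lengths, index=ids), groups=groups_map
    )
    return cm, DETruth(designated=designated, affected=affected)
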