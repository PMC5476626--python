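"""Bulk RNA-seq quantification and differential expression.

Covers RPKM quantification, the expressed-gene floor (group-mean RPKM >= 0.1),
median-of-ratios size factors, a negative-binomial Wald test with
method-of-moments dispersion shrunk toward a log-linear mean-dispersion trend,
Benjamini-Hochberg adjustment per contrast, and the study's DEG call rule
(padj < 0.05 and fold change > 2 or < 0.5) across the four group contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

GROUPS = ("BD3", "CD3", "BD6", "CD6")
#: The four analysed contrasts: between-breed at each age, within-breed across ages.
CONTRASTS: tuple[tuple[str, str], ...] = (
    ("BD3", "CD3"), ("BD6", "CD6"), ("BD3", "BD6"), ("CD3", "CD6")
)
DISPERSION_FLOOR = 1e-8
#: Pseudocount added to both normalized group means for the reported fold
#: change, so zero-count groups yield a finite FC.
FC_PSEUDOCOUNT = 0.5


def contrast_name(contrast: tuple[str, str]) -> str:
    return f"{contrast[0]}v{contrast[1]}"


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, capped at 1)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


@dataclass
class CountMatrix:
    """Gene x sample integer read counts with lengths and group labels."""

    counts: pd.DataFrame            # genes x samples
    lengths: pd.Series              # bp per gene
    groups: dict[str, str]          # sample -> group label
    totals: pd.Series | None = None  # per-sample total mapped reads

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        if self.totals is None:
            self.totals = self.counts.sum(axis=0).astype(float)
        else:
            self.totals = self.totals.reindex(self.counts.columns).astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def group_samples(self, group: str) -> list[str]:
        out = [s for s in self.samples if self.groups[s] == group]
        if not out:
            raise ValueError(f"no samples in group {group!r}")
        return out


def read_counts_tsv(path, groups: dict[str, str]) -> CountMatrix:
    """Read a genes x samples TSV with a ``gene_length`` column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "gene_length" not in df.columns:
        raise ValueError("count table must contain a gene_length column")
    lengths = df["gene_length"].astype(int)
    counts = df.drop(columns=["gene_length"]).astype(int)
    return CountMatrix(counts=counts, lengths=lengths, groups=groups)


def write_counts_tsv(cm: CountMatrix, path) -> None:
    out = cm.counts.copy()
    out.insert(0, "gene_length", cm.lengths)
    out.to_csv(path, sep="\t", index_label="gene_id")


def rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads: count*1e9/(length*total)."""
    if (cm.totals <= 0).any():
        raise ValueError("per-sample totals must be positive for RPKM")
    return cm.counts * 1e9 / np.outer(cm.lengths, cm.totals)


def expressed_filter(
    rpkm_matrix: pd.DataFrame, groups: dict[str, str], floor: float = 0.1
) -> pd.DataFrame:
    """Per-gene, per-group expressed flags: group-mean RPKM >= floor.

    The floor is strict on the "not expressed" side: a group mean of exactly
    ``floor`` counts as expressed.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    labels = sorted(set(groups[s] for s in rpkm_matrix.columns))
    flags = {
        g: rpkm_matrix[[s for s in rpkm_matrix.columns if groups[s] == g]].mean(axis=1)
        >= floor
        for g in labels
    }
    return pd.DataFrame(flags)


def expression_venn(flags: pd.DataFrame) -> dict[str, set[str]]:
    """Per-group unique sets and the all-group shared set from expressed flags."""
    out: dict[str, set[str]] = {}
    for g in flags.columns:
        others = flags.drop(columns=[g])
        out[f"unique_{g}"] = set(flags.index[flags[g] & ~others.any(axis=1)])
    out["shared"] = set(flags.index[flags.all(axis=1)])
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalised to unit geometric mean.

    The reference is the per-gene geometric mean across samples, over genes
    with nonzero counts in every sample.
    """
    x = counts.to_numpy(dtype=float)
    all_nonzero = (x > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; a pseudo-reference "
            "fallback must be configured explicitly"
        )
    logx = np.log(x[all_nonzero])
    log_geomean = logx.mean(axis=1)
    factors = np.exp(np.median(logx - log_geomean[:, None], axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


@dataclass
class DEGResult:
    """Per-gene DE results for one contrast (group A vs group B)."""

    contrast: tuple[str, str]
    table: pd.DataFrame  # baseMeanA, baseMeanB, log2FC, pvalue, padj, deg, direction

    @property
    def name(self) -> str:
        return contrast_name(self.contrast)

    def deg_genes(self) -> dict[str, str]:
        hit = self.table[self.table["deg"]]
        return dict(zip(hit.index, hit["direction"]))


def _moment_dispersions(q: np.ndarray, sizes: list[np.ndarray]) -> np.ndarray:
    """Method-of-moments NB dispersions from normalized counts, pooled within groups."""
    mu = q.mean(axis=1)
    ss = np.zeros(q.shape[0])
    dof = 0
    for idx in sizes:
        sub = q[:, idx]
        ss += sub.var(axis=1, ddof=1) * (len(idx) - 1)
        dof += len(idx) - 1
    s2 = ss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mu) / mu**2
    return np.where(np.isfinite(alpha), alpha, 0.0)


def _trend_dispersions(alpha_raw: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Log-linear mean-dispersion trend fitted to genes above the floor."""
    fit_mask = (alpha_raw > DISPERSION_FLOOR) & (mu > 0)
    if fit_mask.sum() < 10:  # too few informative genes: flat trend
        level = float(np.median(alpha_raw[fit_mask])) if fit_mask.any() else DISPERSION_FLOOR
        return np.full_like(mu, max(level, DISPERSION_FLOOR))
    X = np.log(mu[fit_mask])
    Y = np.log(alpha_raw[fit_mask])
    slope, intercept = np.polyfit(X, Y, 1)
    with np.errstate(divide="ignore"):
        trend = np.exp(intercept + slope * np.log(np.maximum(mu, 1e-8)))
    return np.maximum(trend, DISPERSION_FLOOR)


def nb_de_test(
    cm: CountMatrix,
    contrast: tuple[str, str],
    padj_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> DEGResult:
    """Negative-binomial Wald test for one two-group contrast.

    Counts are normalised by median-of-ratios size factors computed over the
    contrast's samples.  Per-gene dispersion is a method-of-moments estimate
    on normalized counts pooled within the two groups, floored at 1e-8 and
    averaged 50/50 with a fitted log-linear mean-dispersion trend.  The Wald
    statistic uses the delta-method standard error of the log fold change
    under NB variance mu + alpha*mu^2; p-values are two-sided normal and
    BH-adjusted across the genes tested.  Genes with zero counts in every
    sample of the contrast are excluded before testing.  A gene is flagged as
    a DEG when padj < ``padj_threshold`` and the (pseudocounted) fold change
    exceeds ``fc_threshold`` or is below its reciprocal.
    """
    ga, gb = contrast
    sa, sb = cm.group_samples(ga), cm.group_samples(gb)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need at least 2 replicates on each side of the contrast")
    sub = cm.counts[sa + sb]
    tested = sub.sum(axis=1) > 0
    sub = sub[tested]
    sf = size_factors(sub)
    q = (sub / sf).to_numpy(dtype=float)
    ia = np.arange(len(sa))
    ib = np.arange(len(sa), len(sa) + len(sb))

    mu_a, mu_b = q[:, ia].mean(axis=1), q[:, ib].mean(axis=1)
    mu = q.mean(axis=1)
    alpha_raw = np.maximum(_moment_dispersions(q, [ia, ib]), DISPERSION_FLOOR)
    alpha = 0.5 * alpha_raw + 0.5 * _trend_dispersions(alpha_raw, mu)

    inv_sf_a = float((1.0 / sf.iloc[ia.tolist()]).sum())
    inv_sf_b = float((1.0 / sf.iloc[ib.tolist()]).sum())
    var_mu_a = (mu_a * inv_sf_a + len(sa) * alpha * mu_a**2) / len(sa) ** 2
    var_mu_b = (mu_b * inv_sf_b + len(sb) * alpha * mu_b**2) / len(sb) ** 2

    ma, mb = mu_a + FC_PSEUDOCOUNT, mu_b + FC_PSEUDOCOUNT
    log2fc = np.log2(mb / ma)
    se_ln = np.sqrt(var_mu_a / ma**2 + var_mu_b / mb**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_ln > 0, np.log(mb / ma) / se_ln, 0.0)
    pvalue = 2.0 * sps.norm.sf(np.abs(z))
    padj = bh_adjust(pvalue)

    fc = 2.0**log2fc
    deg = (padj < padj_threshold) & ((fc > fc_threshold) | (fc < 1.0 / fc_threshold))
    table = pd.DataFrame(
        {
            "baseMeanA": mu_a, "baseMeanB": mu_b, "log2FC": log2fc,
            "pvalue": pvalue, "padj": padj, "deg": deg,
            "direction": np.where(log2fc > 0, "up", "down"),
        },
        index=sub.index,
    )
    log.info("%s vs %s: %d/%d genes flagged as DEGs", ga, gb, int(deg.sum()), len(table))
    return DEGResult(contrast=contrast, table=table)


def call_deg_sets(results: dict[str, DEGResult]) -> dict[str, object]:
    """Summarise DEG membership across contrasts.

    Returns per-contrast DEG id -> direction maps, per-contrast up/down
    counts, and the within-breed overlap (genes DE in both BD3vBD6 and
    CD3vCD6, the shared developmental set).
    """
    sets = {name: res.deg_genes() for name, res in results.items()}
    counts = {
        name: {
            "up": sum(1 for d in s.values() if d == "up"),
            "down": sum(1 for d in s.values() if d == "down"),
            "total": len(s),
        }
        for name, s in sets.items()
    }
    within = [n for n in ("BD3vBD6", "CD3vCD6") if n in sets]
    overlap = (
        set(sets[within[0]]) & set(sets[within[1]]) if len(within) == 2 else set()
    )
    return {"sets": sets, "counts": counts, "within_breed_overlap": overlap}


def run_all_contrasts(
    cm: CountMatrix,
    contrasts: tuple[tuple[str, str], ...] = CONTRASTS,
    padj_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> dict[str, DEGResult]:
    return {
        contrast_name(c): nb_de_test(cm, c, padj_threshold, fc_threshold)
        for c in contrasts
    }
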