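"""Selection-signature calling from windowed statistics.

The scan Z-transforms window Fst against the genome-wide distribution, sets
empirical nearest-rank tail thresholds, flags windows that are simultaneously
in the upper Z(Fst) tail and the lower Tajima's D tail, merges overlapping or
abutting flagged windows into regions, and maps regions onto gene intervals
to produce the positively-selected-gene (PSG) list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

D_RULES = ("either", "pop1", "pop2", "pooled")


@dataclass
class ThresholdSet:
    """Empirical tail thresholds at the 5% and 1% levels.

    ``z_hi`` maps level -> upper-tail Z(Fst) threshold; ``d_lo`` maps level ->
    {column key -> lower-tail Tajima's D threshold} for each D column the rule
    may consult.
    """

    z_hi: dict[float, float]
    d_lo: dict[float, dict[str, float]]
    level: float

    def __post_init__(self) -> None:
        lv = sorted(self.z_hi)
        for lo, hi in zip(lv, lv[1:]):
            if self.z_hi[lo] < self.z_hi[hi]:
                raise ValueError("1% Z threshold must be more extreme than 5%")


@dataclass
class SweepCall:
    """A merged run of dual-criterion windows and the genes it overlaps."""

    scaffold: str
    start: int
    end: int
    windows: list[tuple[int, int]]
    z_values: list[float]
    d_values: list[float]
    genes: list[str] = field(default_factory=list)


@dataclass
class ScanResult:
    windows: pd.DataFrame          # window table with z_fst and flag columns
    thresholds: ThresholdSet
    calls: list[SweepCall]


def zscore_fst(stats: pd.DataFrame) -> pd.DataFrame:
    """Standardise window Fst genome-wide: z = (fst - mean)/sd (sample sd).

    Windows with undefined Fst stay NaN.  Raises on fewer than two defined
    windows or zero variance.
    """
    fst = stats["fst"].to_numpy(dtype=float)
    defined = ~np.isnan(fst)
    if defined.sum() < 2:
        raise ValueError("need at least 2 windows with defined Fst to Z-score")
    sd = float(np.std(fst[defined], ddof=1))
    if sd == 0.0:
        raise ValueError("window Fst values are all equal; Z-score undefined")
    out = stats.copy()
    out["z_fst"] = (fst - float(np.mean(fst[defined]))) / sd
    out.attrs.update(stats.attrs)
    return out


def empirical_threshold(values, tail: str, level: float) -> float:
    """Nearest-rank empirical tail threshold (no interpolation).

    Upper tail: the nearest-rank ``100*(1-level)`` percentile; a value
    qualifies when >= threshold.  Lower tail: the nearest-rank ``100*level``
    percentile; a value qualifies when <= threshold.
    """
    v = np.sort(np.asarray([x for x in np.ravel(values) if not math.isnan(x)], dtype=float))
    if v.size == 0:
        raise ValueError("empirical_threshold on empty input")
    if not 0.0 < level <= 0.5:
        raise ValueError("level must be in (0, 0.5]")
    if tail == "upper":
        pct = 100.0 * (1.0 - level)
    elif tail == "lower":
        pct = 100.0 * level
    else:
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    rank = max(1, math.ceil(pct / 100.0 * v.size))  # 1-based nearest rank
    return float(v[rank - 1])


def _d_columns(rule: str) -> list[str]:
    if rule == "either":
        return ["D_pop1", "D_pop2"]
    if rule in ("pop1", "pop2"):
        return [f"D_{rule}"]
    if rule == "pooled":
        return ["D_pooled"]
    raise ValueError(f"unknown d_population_rule {rule!r}; expected one of {D_RULES}")


def compute_thresholds(
    stats: pd.DataFrame, d_population_rule: str = "either", level: float = 0.05
) -> ThresholdSet:
    """Z(Fst) upper-tail and Tajima's D lower-tail thresholds at 5% and 1%.

    Thresholds are taken over defined (non-NaN) values only; each D column's
    threshold comes from its own empirical distribution.
    """
    cols = _d_columns(d_population_rule)
    z = stats["z_fst"]
    z_hi = {lv: empirical_threshold(z, "upper", lv) for lv in (0.05, 0.01)}
    d_lo = {
        lv: {c: empirical_threshold(stats[c], "lower", lv) for c in cols}
        for lv in (0.05, 0.01)
    }
    return ThresholdSet(z_hi=z_hi, d_lo=d_lo, level=level)


def call_selected_windows(
    stats: pd.DataFrame,
    level: float = 0.05,
    d_population_rule: str = "either",
    undefined_d_qualifies: bool = False,
) -> ScanResult:
    """Flag dual-criterion windows and merge them into regions.

    A window is called when its Z(Fst) is at or above the upper-tail
    threshold AND its Tajima's D (from the population(s) selected by
    ``d_population_rule``) is at or below that distribution's lower-tail
    threshold.  Under the default ``either`` rule one breed's D suffices.
    Windows with undefined D carry no frequency-spectrum evidence and by
    default do not satisfy the D criterion.  Flagged windows that overlap or
    abut are merged into regions.
    """
    if "z_fst" not in stats.columns:
        stats = zscore_fst(stats)
    if stats["z_fst"].isna().all():
        raise ValueError("no windows with defined Z(Fst)")
    thresholds = compute_thresholds(stats, d_population_rule, level)
    cols = _d_columns(d_population_rule)

    z_ok = stats["z_fst"] >= thresholds.z_hi[level]
    d_ok = pd.Series(False, index=stats.index)
    for c in cols:
        d = stats[c]
        d_ok |= d.notna() & (d <= thresholds.d_lo[level][c])
        if undefined_d_qualifies:
            d_ok |= d.isna()
    flagged = z_ok & d_ok
    out = stats.copy()
    out["z_tail"] = z_ok
    out["d_tail"] = d_ok
    out["selected"] = flagged
    out.attrs.update(stats.attrs)

    calls: list[SweepCall] = []
    d_summary = out[cols].min(axis=1, skipna=True)
    hit = out[flagged].sort_values(["scaffold", "start"])
    for _, row in hit.iterrows():
        w = (int(row["start"]), int(row["end"]))
        if (
            calls
            and calls[-1].scaffold == row["scaffold"]
            and w[0] <= calls[-1].end
        ):
            calls[-1].end = max(calls[-1].end, w[1])
            calls[-1].windows.append(w)
            calls[-1].z_values.append(float(row["z_fst"]))
            calls[-1].d_values.append(float(d_summary[row.name]))
        else:
            calls.append(
                SweepCall(
                    scaffold=str(row["scaffold"]), start=w[0], end=w[1],
                    windows=[w], z_values=[float(row["z_fst"])],
                    d_values=[float(d_summary[row.name])],
                )
            )
    n_flagged = int(flagged.sum())
    log.info(
        "scan: %d/%d windows pass the dual %g%% criterion in %d regions "
        "(Z>=%.4f)", n_flagged, len(stats), 100 * level, len(calls),
        thresholds.z_hi[level],
    )
    return ScanResult(windows=out, thresholds=thresholds, calls=calls)


def map_windows_to_genes(calls: list[SweepCall], annotation: pd.DataFrame) -> pd.DataFrame:
    """Positively selected genes: >= 1 bp overlap with any called region.

    Returns one row per gene (deduplicated) with its supporting regions, the
    peak Z(Fst) and the minimum Tajima's D among supporting windows.  Also
    fills each call's ``genes`` list in place.
    """
    ann = annotation.sort_values(["scaffold", "start"]).reset_index(drop=True)
    if calls and not (set(c.scaffold for c in calls) & set(ann["scaffold"])):
        log.warning("no shared scaffolds between calls and annotation; empty PSG list")
    records: dict[str, dict] = {}
    for call in calls:
        on_scaf = ann[ann["scaffold"] == call.scaffold]
        hits = on_scaf[(on_scaf["start"] < call.end) & (on_scaf["end"] > call.start)]
        call.genes = list(hits["gene_id"])
        for row in hits.itertuples(index=False):
            rec = records.setdefault(
                row.gene_id,
                {
                    "gene_id": row.gene_id, "scaffold": row.scaffold,
                    "gene_start": row.start, "gene_end": row.end,
                    "regions": [], "peak_z_fst": -math.inf, "min_tajima_d": math.inf,
                },
            )
            rec["regions"].append(f"{call.scaffold}:{call.start}-{call.end}")
            rec["peak_z_fst"] = max(rec["peak_z_fst"], max(call.z_values))
            rec["min_tajima_d"] = min(rec["min_tajima_d"], min(call.d_values))
    rows = sorted(records.values(), key=lambda r: (r["scaffold"], r["gene_start"]))
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "scaffold", "gene_start", "gene_end",
            "regions", "peak_z_fst", "min_tajima_d",
        ],
    )
    if not df.empty:
        df["n_regions"] = df["regions"].map(len)
        df["regions"] = df["regions"].map(",".join)
    else:
        df["n_regions"] = pd.Series(dtype=int)
    return df
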