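"""Phenotype formulas: muscle-fibre morphometry and qPCR relative expression.

Fibre density is count per field area, d = N/S (fibres/mm^2).  Fibre diameter
treats the mean cross-section of 50 fibres as a circle,
D = 2*sqrt(Si/(50*pi)) in micrometres, where Si is the summed cross-section
area of 50 fibres in um^2.  Relative qPCR expression uses the 2^-ddCt method
against a reference gene (GAPDH in the study) and a calibrator group.
Group summaries report mean +/- standard error with pairwise Welch tests.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


def fibre_density(N, S) -> float:
    """Fibres per mm^2 from a count N in a field of area S (mm^2)."""
    N = np.asarray(N, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(S <= 0):
        raise ValueError("field area S must be positive")
    if np.any(N < 0):
        raise ValueError("fibre count N must be >= 0")
    out = N / S
    return float(out) if out.ndim == 0 else out


def fibre_diameter(Si) -> float:
    """Fibre diameter (um) from the summed area of 50 fibres Si (um^2)."""
    Si = np.asarray(Si, dtype=float)
    if np.any(Si <= 0):
        raise ValueError("summed fibre area Si must be positive")
    out = 2.0 * np.sqrt(Si / (50.0 * math.pi))
    return float(out) if out.ndim == 0 else out


def ddct(records: pd.DataFrame, calibrator_group: str) -> pd.DataFrame:
    """Relative expression by 2^-ddCt.

    ``records`` needs columns ``sample``, ``group``, ``ct_target``,
    ``ct_reference`` (technical replicates as repeated rows, averaged on the
    Ct scale first).  dCt = Ct_target - Ct_reference per sample; ddCt
    subtracts the calibrator group's mean dCt; RQ = 2^-ddCt.
    """
    required = {"sample", "group", "ct_target", "ct_reference"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns {sorted(missing)}")
    if records[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct values")
    per_sample = (
        records.groupby(["sample", "group"], sort=False)[["ct_target", "ct_reference"]]
        .mean()
        .reset_index()
    )
    per_sample["dct"] = per_sample["ct_target"] - per_sample["ct_reference"]
    cal = per_sample.loc[per_sample["group"] == calibrator_group, "dct"]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    per_sample["ddct"] = per_sample["dct"] - cal.mean()
    per_sample["rq"] = 2.0 ** (-per_sample["ddct"])
    return per_sample


def group_summary(
    values, groups, test: str = "welch", bonferroni: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean +/- SE per group plus pairwise two-group comparisons.

    Returns (summary, comparisons).  SE is sd/sqrt(n) and is flagged
    undefined (NaN) for groups of size < 2.  Pairwise p-values use Welch's
    t-test by default (``test='student'`` pools variances), optionally
    Bonferroni-corrected across the comparisons, and are flagged at 0.05 and
    0.01.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    rows = []
    for g, sub in df.groupby("group", sort=False):
        n = len(sub)
        rows.append(
            {
                "group": g,
                "n": n,
                "mean": sub["value"].mean(),
                "se": sub["value"].std(ddof=1) / math.sqrt(n) if n >= 2 else math.nan,
                "se_defined": n >= 2,
            }
        )
    summary = pd.DataFrame(rows)

    comps = []
    pairs = list(combinations(summary["group"], 2))
    for a, b in pairs:
        va = df.loc[df["group"] == a, "value"]
        vb = df.loc[df["group"] == b, "value"]
        if len(va) < 2 or len(vb) < 2:
            p = math.nan
        elif va.var(ddof=1) == 0 and vb.var(ddof=1) == 0 and va.mean() == vb.mean():
            p = 1.0
        else:
            p = float(
                sps.ttest_ind(va, vb, equal_var=(test == "student")).pvalue
            )
        comps.append({"group_a": a, "group_b": b, "pvalue": p})
    comparisons = pd.DataFrame(comps, columns=["group_a", "group_b", "pvalue"])
    if not comparisons.empty:
        padj = comparisons["pvalue"] * (len(pairs) if bonferroni else 1)
        comparisons["p_adjusted"] = padj.clip(upper=1.0)
        comparisons["significant_05"] = comparisons["p_adjusted"] < 0.05
        comparisons["significant_01"] = comparisons["p_adjusted"] < 0.01
    return summary, comparisons
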