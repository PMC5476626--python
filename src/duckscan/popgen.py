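"""Windowed population-genetic statistics.

Implements the scan's building blocks: sliding windows, per-site pairwise
nucleotide diversity (pi), Watterson's theta via segregating sites, Tajima's D
with the Tajima (1989) normalising constants, and two-population Fst with a
Weir & Cockerham (1984) ratio-of-averages estimator (default) or the
sample-corrected Hudson estimator.

Windows are 0-based half-open intervals on a scaffold.  Statistics that are
undefined for a window (no segregating sites, empty denominator) are returned
as NaN rather than raising, so a genome scan can carry them as flagged
missing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import AlleleCountTable, ScaffoldIndex, VariantTable, allele_counts

DEFAULT_WINDOW = 40_000
DEFAULT_STEP = 20_000

#: Sites where a population has fewer called alleles than this are excluded
#: from that window's statistics (minimum for the pairwise terms).
DEFAULT_MIN_CALLED = 4


@dataclass(frozen=True)
class Window:
    scaffold: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad window [{self.start}, {self.end})")


def sliding_windows(
    scaffold_length: int,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    scaffold: str = "",
) -> list[Window]:
    """Sliding windows starting at 0, step, 2*step, ...

    Only full windows (``end <= scaffold_length``) are emitted, so the count
    is ``floor((L - window)/step) + 1`` for ``L >= window`` and 0 otherwise.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if step > window:
        raise ValueError("step must not exceed the window size")
    out = []
    start = 0
    while start + window <= scaffold_length:
        out.append(Window(scaffold, start, start + window))
        start += step
    return out


def _window_mask(ac: AlleleCountTable, window: Window) -> np.ndarray:
    return (
        (ac.scaffold == window.scaffold)
        & (ac.pos >= window.start)
        & (ac.pos < window.end)
    )


def _pi_per_site(c: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Unbiased per-site pairwise diversity 2c(n-c)/(n(n-1)); needs n >= 2."""
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    return 2.0 * c * (n - c) / (n * (n - 1.0))


def nucleotide_diversity(ac: AlleleCountTable, window: Window) -> float:
    """Sum of per-site pairwise diversity over in-window sites.

    Sites with fewer than two called alleles are skipped.
    """
    m = _window_mask(ac, window) & (ac.n_called >= 2)
    if not m.any():
        return 0.0
    return float(_pi_per_site(ac.c_alt[m], ac.n_called[m]).sum())


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalising constants for a sample of n sequences."""
    if n < 4:
        raise ValueError("Tajima's D requires at least 4 sequences")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    return {
        "a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
        "e1": c1 / a1, "e2": c2 / (a1**2 + a2),
    }


def _tajima_from_counts(c: np.ndarray, n_called: np.ndarray) -> tuple[int, float, float]:
    """(S, pi, D) from allele counts sharing a single sample size.

    The window's modal ``n_called`` is used; sites with a different
    ``n_called`` are excluded so the constants see one sample size.
    Returns ``D = NaN`` when no site segregates.
    """
    if c.size == 0:
        return 0, 0.0, math.nan
    ns, freq = np.unique(n_called, return_counts=True)
    n = int(ns[np.argmax(freq)])  # modal n; ties -> smaller n (np.unique is sorted)
    if n < 4:
        raise ValueError(f"modal sample size {n} < 4; cannot compute Tajima's D")
    keep = n_called == n
    c = c[keep]
    seg = (c > 0) & (c < n)
    S = int(seg.sum())
    pi = float(_pi_per_site(c[seg], np.full(seg.sum(), n)).sum()) if S else 0.0
    if S == 0:
        return 0, 0.0, math.nan
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    D = (pi - S / k["a1"]) / math.sqrt(var)
    return S, pi, float(D)


def tajimas_d(ac: AlleleCountTable, window: Window, min_called: int = DEFAULT_MIN_CALLED) -> float:
    """Tajima's D over in-window sites (NaN when no site segregates)."""
    m = _window_mask(ac, window) & (ac.n_called >= max(min_called, 2))
    _, _, D = _tajima_from_counts(ac.c_alt[m], ac.n_called[m])
    return D


# ---------------------------------------------------------------------------
# Fst


def _wc_components(
    p1: np.ndarray, n1: np.ndarray, h1: np.ndarray,
    p2: np.ndarray, n2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir & Cockerham (1984) per-site variance components for two populations.

    ``n`` are sampled individuals, ``p`` ALT allele frequencies and ``h``
    observed heterozygote frequencies.  Returns the ``a`` (between-population),
    ``b`` (between-individual) and ``c`` (within-individual) components.
    """
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def _hudson_components(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sample-corrected Hudson numerator/denominator (allele counts n)."""
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1.0)
        - p2 * (1 - p2) / (n2 - 1.0)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _fst_site_components(
    ac1: AlleleCountTable, ac2: AlleleCountTable, estimator: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (numerator, denominator) arrays for the chosen estimator."""
    if estimator == "wc":
        with np.errstate(divide="ignore", invalid="ignore"):
            a, b, c = _wc_components(
                ac1.c_alt / ac1.n_called, ac1.n_ind.astype(float),
                ac1.n_het / np.maximum(ac1.n_ind, 1),
                ac2.c_alt / ac2.n_called, ac2.n_ind.astype(float),
                ac2.n_het / np.maximum(ac2.n_ind, 1),
            )
        return a, a + b + c
    if estimator == "hudson":
        with np.errstate(divide="ignore", invalid="ignore"):
            return _hudson_components(
                ac1.c_alt / ac1.n_called, ac1.n_called.astype(float),
                ac2.c_alt / ac2.n_called, ac2.n_called.astype(float),
            )
    raise ValueError(f"unknown Fst estimator {estimator!r} (expected 'wc' or 'hudson')")


def fst_window(
    ac1: AlleleCountTable,
    ac2: AlleleCountTable,
    window: Window,
    estimator: str = "wc",
    min_called: int = DEFAULT_MIN_CALLED,
) -> float:
    """Window Fst as a ratio of per-site component sums (ratio of averages).

    NaN when the window has no usable site or a zero denominator.
    """
    num, den = _fst_site_components(ac1, ac2, estimator)
    m = (
        _window_mask(ac1, window)
        & (ac1.n_called >= min_called)
        & (ac2.n_called >= min_called)
    )
    if not m.any():
        return math.nan
    num_sum, den_sum = float(np.nansum(num[m])), float(np.nansum(den[m]))
    if den_sum == 0.0:
        return math.nan
    return num_sum / den_sum


# ---------------------------------------------------------------------------
# Whole-genome window table

WINDOW_STAT_COLUMNS = [
    "scaffold", "start", "end", "n_sites",
    "S_pop1", "pi_pop1", "D_pop1",
    "S_pop2", "pi_pop2", "D_pop2",
    "D_pooled", "fst",
]


def window_stats(
    vt: VariantTable,
    pop1: str,
    pop2: str,
    scaffold_index: ScaffoldIndex,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    estimator: str = "wc",
    min_called: int = DEFAULT_MIN_CALLED,
) -> pd.DataFrame:
    """Per-window S/pi/Tajima's D for each population (and pooled) plus Fst.

    Only scaffolds retained in ``scaffold_index`` are scanned.  Sites where
    either population has fewer than ``min_called`` called alleles are
    excluded from every statistic.  The returned frame carries the population
    labels in ``df.attrs``.
    """
    ac1 = allele_counts(vt, pop1)
    ac2 = allele_counts(vt, pop2)
    acp = allele_counts(vt, None)
    usable = (ac1.n_called >= min_called) & (ac2.n_called >= min_called)
    num, den = _fst_site_components(ac1, ac2, estimator)

    rows = []
    for scaf in scaffold_index.retained_ids():
        m = (vt.scaffold == scaf) & usable
        pos = vt.pos[m]
        c1, n1 = ac1.c_alt[m], ac1.n_called[m]
        c2, n2 = ac2.c_alt[m], ac2.n_called[m]
        cp, np_ = acp.c_alt[m], acp.n_called[m]
        w_num, w_den = num[m], den[m]
        for w in sliding_windows(scaffold_index.lengths[scaf], window, step, scaf):
            lo, hi = np.searchsorted(pos, [w.start, w.end])
            sl = slice(lo, hi)
            S1, pi1, D1 = _tajima_from_counts(c1[sl], n1[sl])
            S2, pi2, D2 = _tajima_from_counts(c2[sl], n2[sl])
            _, _, Dp = _tajima_from_counts(cp[sl], np_[sl])
            ns, ds = float(np.nansum(w_num[sl])), float(np.nansum(w_den[sl]))
            fst = ns / ds if (hi > lo and ds != 0.0) else math.nan
            rows.append(
                (scaf, w.start, w.end, hi - lo, S1, pi1, D1, S2, pi2, D2, Dp, fst)
            )
    df = pd.DataFrame(rows, columns=WINDOW_STAT_COLUMNS)
    df.attrs["pop1"] = pop1
    df.attrs["pop2"] = pop2
    df.attrs["estimator"] = estimator
    return df
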