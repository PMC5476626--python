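"""Windowed statistics against independent oracles and closed forms."""

import itertools
import math

import numpy as np
import pytest

from duckscan.popgen import (
    Window, fst_window, nucleotide_diversity, sliding_windows, tajima_constants,
    tajimas_d, window_stats,
)
from duckscan.synthetic_data import SimGenotypeConfig, simulate_two_pop_genotypes
from duckscan.variant_io import ScaffoldIndex

from conftest import act_from_counts, act_from_genotypes


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_pi(counts, n):
    """Mean pairwise difference summed over sites, by explicit haplotype pairs."""
    total = 0.0
    for c in counts:
        hap = [1] * c + [0] * (n - c)
        diffs = sum(a != b for a, b in itertools.combinations(hap, 2))
        total += diffs / math.comb(n, 2)
    return total


def brute_force_tajima(counts, n):
    """Tajima's D via explicit pairwise pi and directly evaluated constants."""
    S = sum(1 for c in counts if 0 < c < n)
    if S == 0:
        return math.nan
    pi = brute_force_pi([c for c in counts if 0 < c < n], n)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i / i for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def wc_fst_oracle(g1, g2):
    """Weir & Cockerham two-population Fst, coded scalar directly from the
    1984 variance-component equations, ratio of averages over sites."""
    num = den = 0.0
    for s in range(g1.shape[0]):
        n1, n2 = g1.shape[1], g2.shape[1]
        p1 = g1[s].sum() / (2 * n1)
        p2 = g2[s].sum() / (2 * n2)
        h1 = sum(1 for i in range(n1) if g1[s, i, 0] != g1[s, i, 1]) / n1
        h2 = sum(1 for i in range(n2) if g2[s, i, 0] != g2[s, i, 1]) / n2
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


WINDOW_ALL = Window("s1", 0, 10_000)


# ---------------------------------------------------------------------------
# sliding windows

@pytest.mark.parametrize(
    "L, expected_starts",
    [
        (100_000, [0, 20_000, 40_000, 60_000]),
        (39_999, []),
        (40_000, [0]),
        (59_999, [0]),
        (60_000, [0, 20_000]),
    ],
)
def test_sliding_window_starts(L, expected_starts):
    wins = sliding_windows(L, 40_000, 20_000)
    assert [w.start for w in wins] == expected_starts
    assert all(w.end - w.start == 40_000 for w in wins)
    assert len(wins) == (math.floor((L - 40_000) / 20_000) + 1 if L >= 40_000 else 0)


def test_sliding_window_rejects_bad_sizes():
    with pytest.raises(ValueError):
        sliding_windows(100_000, 0, 10)
    with pytest.raises(ValueError):
        sliding_windows(100_000, 10_000, 0)
    with pytest.raises(ValueError):
        sliding_windows(100_000, 10_000, 20_000)


# ---------------------------------------------------------------------------
# pi

def test_pi_single_site_direct_formula():
    act = act_from_counts([3], [6])
    assert nucleotide_diversity(act, WINDOW_ALL) == pytest.approx(0.6, abs=1e-12)


def test_pi_monomorphic_window_is_zero():
    act = act_from_counts([0, 6], [6, 6])
    assert nucleotide_diversity(act, WINDOW_ALL) == 0.0


def test_pi_additive_over_sites_and_windows():
    act = act_from_counts([3, 3], [6, 6], positions=[10, 5_010])
    full = nucleotide_diversity(act, WINDOW_ALL)
    left = nucleotide_diversity(act, Window("s1", 0, 5_000))
    right = nucleotide_diversity(act, Window("s1", 5_000, 10_000))
    assert full == pytest.approx(2 * 0.6, abs=1e-12)
    assert full == pytest.approx(left + right, abs=1e-12)


def test_pi_matches_brute_force_pairwise_count():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = int(rng.integers(4, 21))
        counts = rng.integers(1, n, size=int(rng.integers(1, 30)))
        act = act_from_counts(counts, np.full(counts.size, n))
        assert nucleotide_diversity(act, WINDOW_ALL) == pytest.approx(
            brute_force_pi(counts, n), abs=1e-10
        )


# ---------------------------------------------------------------------------
# Tajima's D

def test_tajima_undefined_without_segregating_sites():
    act = act_from_counts([0, 6], [6, 6])
    assert math.isnan(tajimas_d(act, WINDOW_ALL))


def test_tajima_zero_when_pi_equals_watterson():
    # n=4: 8 singletons (pi 1/2 each) + 3 doubletons (pi 2/3 each)
    # gives pi = 6 = S/a1 = 11/(11/6), so the numerator is exactly zero.
    counts = [1] * 8 + [2] * 3
    act = act_from_counts(counts, [4] * 11)
    assert tajimas_d(act, WINDOW_ALL) == pytest.approx(0.0, abs=1e-12)


def test_tajima_worked_example_n4():
    # n=4 sequences, 3 sites with minor-allele counts {1,1,2}:
    # a1=11/6, theta_W=1.6364, pi=10/6 -> D ~ 0.1677
    act = act_from_counts([1, 1, 2], [4, 4, 4])
    d = tajimas_d(act, WINDOW_ALL)
    assert d == pytest.approx(0.1677, abs=1e-3)
    assert d == pytest.approx(brute_force_tajima([1, 1, 2], 4), abs=1e-10)


def test_tajima_requires_four_sequences():
    act = act_from_counts([1], [3])
    with pytest.raises(ValueError):
        tajimas_d(act, WINDOW_ALL, min_called=2)


def test_tajima_matches_brute_force_on_random_windows():
    rng = np.random.default_rng(11)
    for _ in range(200):
        n = int(rng.integers(4, 21))
        S = int(rng.integers(1, 51))
        counts = rng.integers(1, n, size=S)
        act = act_from_counts(counts, np.full(S, n))
        assert tajimas_d(act, WINDOW_ALL) == pytest.approx(
            brute_force_tajima(counts, n), abs=1e-10
        )


def test_tajima_uses_modal_sample_size():
    # 10 sites at n=6 plus one deviant site at n=4: the deviant site must be
    # excluded, leaving the same D as the n=6-only window.
    counts6 = [1, 2, 3, 1, 5, 2, 4, 1, 2, 3]
    act_clean = act_from_counts(counts6, [6] * 10)
    act_mixed = act_from_counts(counts6 + [1], [6] * 10 + [4])
    assert tajimas_d(act_mixed, WINDOW_ALL) == pytest.approx(
        tajimas_d(act_clean, WINDOW_ALL), abs=1e-12
    )


def test_tajima_constants_hand_values_n4():
    k = tajima_constants(4)
    assert k["a1"] == pytest.approx(11 / 6, abs=1e-12)
    assert k["c1"] == pytest.approx(1 / 99, abs=1e-12)


# ---------------------------------------------------------------------------
# Fst

def test_wc_fst_matches_independent_oracle():
    rng = np.random.default_rng(3)
    for _ in range(30):
        g1 = rng.integers(0, 2, size=(5, 8, 2))
        g2 = rng.integers(0, 2, size=(5, 8, 2))
        # keep sites polymorphic overall so the denominator is nonzero
        if (g1.sum() + g2.sum()) in (0, 5 * 16 * 2):
            continue
        act1, act2 = act_from_genotypes(g1), act_from_genotypes(g2)
        assert fst_window(act1, act2, WINDOW_ALL, "wc") == pytest.approx(
            wc_fst_oracle(g1, g2), abs=1e-10
        )


def test_hudson_fixed_difference_is_one():
    a = act_from_counts([18, 18], [18, 18])
    b = act_from_counts([0, 0], [18, 18])
    assert fst_window(a, b, WINDOW_ALL, "hudson") == pytest.approx(1.0, abs=1e-12)


def test_hudson_identical_tables_closed_form():
    # The sample-corrected Hudson estimator gives exactly -1/(n-1) on
    # identical polymorphic tables (zero differentiation in expectation).
    a = act_from_counts([3, 5, 9], [18, 18, 18])
    assert fst_window(a, a, WINDOW_ALL, "hudson") == pytest.approx(-1 / 17, abs=1e-12)


def test_fst_unknown_estimator_rejected():
    a = act_from_counts([3], [18])
    with pytest.raises(ValueError):
        fst_window(a, a, WINDOW_ALL, "nei")


def test_statistics_invariant_to_ref_alt_relabel():
    rng = np.random.default_rng(5)
    g1 = rng.integers(0, 2, size=(20, 6, 2))
    g2 = rng.integers(0, 2, size=(20, 6, 2))
    act1, act2 = act_from_genotypes(g1), act_from_genotypes(g2)
    f1, f2 = act_from_genotypes(1 - g1), act_from_genotypes(1 - g2)
    assert nucleotide_diversity(act1, WINDOW_ALL) == pytest.approx(
        nucleotide_diversity(f1, WINDOW_ALL), abs=1e-12
    )
    assert tajimas_d(act1, WINDOW_ALL) == pytest.approx(
        tajimas_d(f1, WINDOW_ALL), abs=1e-12
    )
    for est in ("wc", "hudson"):
        assert fst_window(act1, act2, WINDOW_ALL, est) == pytest.approx(
            fst_window(f1, f2, WINDOW_ALL, est), abs=1e-12
        )


def test_null_simulation_windowed_wc_matches_balding_nichols():
    """Genome-wide mean windowed WC Fst ~ the Balding-Nichols F under the null."""
    cfg = SimGenotypeConfig(seed=2, sweep_windows=())
    vt, _ = simulate_two_pop_genotypes(cfg)
    stats = window_stats(vt, "BD", "CD", ScaffoldIndex(lengths=cfg.scaffold_lengths))
    assert len(stats) >= 2000
    assert stats["fst"].mean() == pytest.approx(cfg.baseline_fst, abs=0.02)


def test_window_stats_columns_and_counts(tiny_variant_table):
    idx = ScaffoldIndex(lengths={"s1": 1_000})
    df = window_stats(
        tiny_variant_table, "BD", "CD", idx, window=1_000, step=1_000
    )
    assert len(df) == 1
    assert df.loc[0, "n_sites"] == 3
    assert df.attrs["pop1"] == "BD"
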