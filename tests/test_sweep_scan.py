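"""Z-transform, empirical thresholds, dual-criterion calls and gene mapping."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duckscan.sweep_scan import (
    call_selected_windows, compute_thresholds, empirical_threshold,
    map_windows_to_genes, zscore_fst, SweepCall,
)


def make_stats(n=100, seed=0, scaffold="s1"):
    """Toy window table: mild null with controllable injections."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "scaffold": [scaffold] * n,
            "start": np.arange(n) * 20_000,
            "end": np.arange(n) * 20_000 + 40_000,
            "n_sites": 40,
            "S_pop1": 10, "pi_pop1": 3.0, "D_pop1": rng.normal(1.0, 0.3, n),
            "S_pop2": 10, "pi_pop2": 3.0, "D_pop2": rng.normal(1.0, 0.3, n),
            "D_pooled": rng.normal(1.0, 0.3, n),
            "fst": rng.normal(0.05, 0.02, n),
        }
    )
    return df


def test_zscore_standardises_to_unit_moments():
    df = zscore_fst(make_stats())
    assert df["z_fst"].mean() == pytest.approx(0.0, abs=1e-9)
    assert df["z_fst"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_zscore_hand_example_sample_sd():
    df = make_stats(3)
    df["fst"] = [0.0, 0.1, 0.2]
    assert list(zscore_fst(df)["z_fst"]) == pytest.approx([-1.0, 0.0, 1.0], abs=1e-12)


def test_zscore_degenerate_input_errors():
    df = make_stats(5)
    df["fst"] = 0.3
    with pytest.raises(ValueError):
        zscore_fst(df)


def test_zscore_preserves_undefined_windows():
    df = make_stats(10)
    df.loc[3, "fst"] = np.nan
    out = zscore_fst(df)
    assert math.isnan(out.loc[3, "z_fst"])
    assert out["z_fst"].notna().sum() == 9


@pytest.mark.parametrize(
    "values, tail, level, expected",
    [
        (list(range(1, 101)), "upper", 0.05, 95),
        (list(range(1, 101)), "lower", 0.01, 1),
        ([42.0], "upper", 0.05, 42.0),
        ([42.0], "lower", 0.5, 42.0),
    ],
)
def test_empirical_threshold_nearest_rank(values, tail, level, expected):
    assert empirical_threshold(values, tail, level) == expected


def test_empirical_threshold_qualifying_set_size():
    thr = empirical_threshold(list(range(1, 101)), "upper", 0.05)
    assert sum(1 for v in range(1, 101) if v >= thr) >= 5


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(
        st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
        min_size=1, max_size=300,
    ),
    st.floats(0.01, 0.5),
)
def test_empirical_threshold_tail_mass_property(values, level):
    """The qualifying set always carries at least the nominal tail mass."""
    hi = empirical_threshold(values, "upper", level)
    lo = empirical_threshold(values, "lower", level)
    n = len(values)
    assert sum(v >= hi for v in values) >= math.floor(level * n)
    assert sum(v <= lo for v in values) >= math.floor(level * n)
    assert lo <= empirical_threshold(values, "lower", 0.5)


def test_empirical_threshold_empty_errors():
    with pytest.raises(ValueError):
        empirical_threshold([], "upper", 0.05)


def test_threshold_set_one_percent_more_extreme():
    df = zscore_fst(make_stats(500, seed=3))
    ts = compute_thresholds(df)
    assert ts.z_hi[0.01] >= ts.z_hi[0.05]
    for c in ("D_pop1", "D_pop2"):
        assert ts.d_lo[0.01][c] <= ts.d_lo[0.05][c]


def _inject(df, rows, z=10.0, d=-3.0, which="both"):
    for i in rows:
        if which in ("both", "z"):
            df.loc[i, "fst"] = 0.05 + z * 0.02
        if which in ("both", "d"):
            df.loc[i, "D_pop1"] = d
    return df


def test_dual_criterion_is_a_conjunction():
    df = _inject(make_stats(200, seed=1), [10], which="z")
    res = call_selected_windows(zscore_fst(df))
    assert not res.windows.loc[10, "selected"]  # Z tail only
    assert res.windows.loc[10, "z_tail"]


def test_consecutive_flagged_windows_merge_into_one_region():
    df = _inject(make_stats(200, seed=2), [0, 1, 2])
    res = call_selected_windows(zscore_fst(df))
    regions = [c for c in res.calls if c.start == 0]
    assert len(regions) == 1
    assert (regions[0].start, regions[0].end) == (0, 80_000)
    assert len(regions[0].windows) == 3


def test_tightening_level_never_adds_calls():
    df = _inject(make_stats(400, seed=4), [5, 50, 100, 200])
    stats = zscore_fst(df)
    sel5 = set(call_selected_windows(stats, level=0.05).windows.query("selected").index)
    sel1 = set(call_selected_windows(stats, level=0.01).windows.query("selected").index)
    assert sel1 <= sel5


def test_called_set_within_tail_intersection():
    df = _inject(make_stats(300, seed=5), [7, 8, 120])
    res = call_selected_windows(zscore_fst(df))
    w = res.windows
    assert (w["selected"] <= (w["z_tail"] & w["d_tail"])).all()


def test_regions_disjoint_sorted_and_cover_members():
    df = _inject(make_stats(300, seed=6), [3, 4, 90, 200, 201, 202])
    res = call_selected_windows(zscore_fst(df))
    calls = res.calls
    for a, b in zip(calls, calls[1:]):
        if a.scaffold == b.scaffold:
            assert a.end <= b.start
    for c in calls:
        assert c.start == min(w[0] for w in c.windows)
        assert c.end == max(w[1] for w in c.windows)


def test_undefined_d_windows_do_not_qualify_by_default():
    df = _inject(make_stats(200, seed=7), [10], which="z")
    df.loc[10, ["D_pop1", "D_pop2"]] = np.nan
    res = call_selected_windows(zscore_fst(df))
    assert not res.windows.loc[10, "selected"]
    res2 = call_selected_windows(zscore_fst(df), undefined_d_qualifies=True)
    assert res2.windows.loc[10, "selected"]


def test_d_population_rule_variants():
    df = _inject(make_stats(200, seed=8), [10], which="z")
    df.loc[10, "D_pop2"] = -5.0  # only pop2 in the low tail
    stats = zscore_fst(df)
    assert call_selected_windows(stats, d_population_rule="either").windows.loc[10, "selected"]
    assert call_selected_windows(stats, d_population_rule="pop2").windows.loc[10, "selected"]
    assert not call_selected_windows(stats, d_population_rule="pop1").windows.loc[10, "selected"]
    with pytest.raises(ValueError):
        call_selected_windows(stats, d_population_rule="pop3")


# ---------------------------------------------------------------------------
# gene mapping

ANN = pd.DataFrame(
    {
        "gene_id": ["g1", "g2", "g3"],
        "scaffold": ["s1", "s1", "s1"],
        "start": [50_000, 80_000, 300_000],
        "end": [55_000, 95_000, 305_000],
        "strand": ["+", "-", "+"],
    }
)


def _call(scaffold, start, end):
    return SweepCall(scaffold=scaffold, start=start, end=end,
                     windows=[(start, end)], z_values=[3.0], d_values=[-2.0])


def test_gene_overlapping_region_is_psg():
    psgs = map_windows_to_genes([_call("s1", 0, 80_000)], ANN)
    assert list(psgs["gene_id"]) == ["g1"]


def test_gene_abutting_region_end_is_not_psg():
    # g2 starts exactly at the region end: half-open intervals do not overlap
    psgs = map_windows_to_genes([_call("s1", 0, 80_000)], ANN)
    assert "g2" not in set(psgs["gene_id"])


def test_gene_hit_by_two_regions_listed_once():
    calls = [_call("s1", 40_000, 52_000), _call("s1", 54_000, 60_000)]
    psgs = map_windows_to_genes(calls, ANN)
    assert list(psgs["gene_id"]) == ["g1"]
    assert psgs.loc[0, "n_regions"] == 2


def test_psg_list_invariant_under_annotation_order():
    calls = [_call("s1", 0, 100_000)]
    shuffled = ANN.sample(frac=1, random_state=9)
    a = map_windows_to_genes(calls, ANN)
    b = map_windows_to_genes(calls, shuffled)
    assert list(a["gene_id"]) == list(b["gene_id"])


def test_scaffold_mismatch_yields_empty(caplog):
    psgs = map_windows_to_genes([_call("chrZ", 0, 80_000)], ANN)
    assert psgs.empty
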