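import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vfpoint import geometry, simulate
from vfpoint.geometry import Eye, N_LOCATIONS
from vfpoint.metrics import Cohort
from vfpoint.pointwise import (
    BinSpec,
    assign_bin,
    change_by_bin,
    effect_size,
    location_mean_map,
    map_to_grid,
    match_points,
    md_stratum,
    range_subset_stats,
    round_half_away,
)
from conftest import make_exam


def _points(changes, baselines=None, **cols):
    n = len(changes)
    base = baselines if baselines is not None else [-12.0] * n
    df = pd.DataFrame(
        {
            "patient_id": cols.get("patient_id", [f"P{i}" for i in range(n)]),
            "eye": ["right"] * n,
            "loc_index": list(range(n)),
            "baseline_td_db": base,
            "change_db": changes,
            "arm": cols.get("arm", ["cwi"] * n),
            "on_acetazolamide": cols.get("acz", [False] * n),
        }
    )
    df["followup_td_db"] = df["baseline_td_db"] + df["change_db"]
    return df


# --- binning ---------------------------------------------------------------

@pytest.mark.parametrize(
    "td,expected",
    [
        (-12.0, "(-15, -10)"),
        (-10.0, "(-10, -5)"),   # half-open: boundary goes to the upper bin
        (-35.0, "(-35, -30)"),
        (-35.01, None),
        (9.99, "(5, 10)"),
        (10.0, None),
        (12.0, None),
        (np.nan, None),
    ],
)
def test_assign_bin(td, expected):
    assert assign_bin(td) == expected


def test_binspec_validates_edges():
    with pytest.raises(ValueError):
        BinSpec(edges=(0.0,))
    with pytest.raises(ValueError):
        BinSpec(edges=(0.0, -5.0))


def test_round_half_away():
    assert round_half_away(1.25, 1) == 1.3
    assert round_half_away(-1.25, 1) == -1.3
    assert round_half_away(2.5, 0) == 3.0
    assert round_half_away(-2.5, 0) == -3.0
    assert round_half_away(1.234, 2) == 1.23


# --- matching --------------------------------------------------------------

def test_match_points_full_pair_yields_104(flat_model):
    s = np.full(N_LOCATIONS, 25.0)
    cohort = Cohort.from_exams([
        make_exam("P1", Eye.RIGHT, 0, s), make_exam("P1", Eye.LEFT, 0, s),
        make_exam("P1", Eye.RIGHT, 12, s), make_exam("P1", Eye.LEFT, 12, s),
    ])
    pts = match_points(cohort, flat_model, 12)
    assert len(pts) == 104  # 2 eyes x 52 analyzable locations


def test_match_points_missing_followup_contributes_nothing(flat_model):
    s = np.full(N_LOCATIONS, 25.0)
    cohort = Cohort.from_exams([
        make_exam("P1", Eye.RIGHT, 0, s),
        make_exam("P2", Eye.RIGHT, 0, s), make_exam("P2", Eye.RIGHT, 12, s),
    ])
    pts = match_points(cohort, flat_model, 12)
    assert set(pts["patient_id"]) == {"P2"}
    assert len(pts) == 52


def test_match_points_change_is_followup_minus_baseline(flat_model):
    s0 = np.full(N_LOCATIONS, 18.0)   # td -12
    s1 = np.full(N_LOCATIONS, 26.0)   # td -4
    cohort = Cohort.from_exams([
        make_exam("P1", Eye.RIGHT, 0, s0), make_exam("P1", Eye.RIGHT, 12, s1),
    ])
    pts = match_points(cohort, flat_model, 12)
    assert np.allclose(pts["baseline_td_db"], -12.0)
    assert np.allclose(pts["change_db"], 8.0)


def test_match_points_excludes_unreliable_exams(flat_model):
    s = np.full(N_LOCATIONS, 25.0)
    cohort = Cohort.from_exams([
        make_exam("P1", Eye.RIGHT, 0, s),
        make_exam("P1", Eye.RIGHT, 12, s, fp=0.2),
    ])
    assert len(match_points(cohort, flat_model, 12)) == 0
    assert len(match_points(cohort, flat_model, 12, reliable_only=False)) == 52


# --- per-bin change --------------------------------------------------------

def test_change_by_bin_hand_statistics():
    tab = change_by_bin(_points([1.0, 2.0, 3.0]), BinSpec(min_observations=1))
    row = tab[tab["bin"] == "(-15, -10)"].iloc[0]
    assert row["n_points"] == 3
    assert row["mean_change_db"] == pytest.approx(2.0)
    assert row["sd_change_db"] == pytest.approx(1.0)  # n-1 denominator
    assert row["mean_baseline_db"] == pytest.approx(-12.0)


def test_change_by_bin_zero_changes_degenerate_ci():
    tab = change_by_bin(_points([0.0] * 12), BinSpec(min_observations=10))
    row = tab[tab["bin"] == "(-15, -10)"].iloc[0]
    assert row["mean_change_db"] == 0.0 and row["sd_change_db"] == 0.0
    assert row["ci_low"] == 0.0 and row["ci_high"] == 0.0
    assert bool(row["reported"]) is True


def test_change_by_bin_ci_symmetric_about_mean():
    rng = np.random.default_rng(1)
    tab = change_by_bin(_points(list(rng.normal(2, 3, 40))), BinSpec(min_observations=10))
    row = tab[tab["n_points"] > 0].iloc[0]
    assert (row["ci_low"] + row["ci_high"]) / 2 == pytest.approx(row["mean_change_db"])
    half = 1.96 * row["sd_change_db"] / np.sqrt(row["n_points"])
    assert row["ci_high"] - row["mean_change_db"] == pytest.approx(half)


def test_change_by_bin_suppresses_small_bins_but_retains_rows():
    tab = change_by_bin(_points([1.0] * 5), BinSpec(min_observations=10))
    row = tab[tab["bin"] == "(-15, -10)"].iloc[0]
    assert row["n_points"] == 5 and bool(row["reported"]) is False


@settings(derandomize=True, max_examples=30)
@given(st.lists(st.floats(-40, 15), min_size=1, max_size=200))
def test_bin_partition_conserves_points(baselines):
    pts = _points([0.0] * len(baselines), baselines)
    spec = BinSpec()
    tab = change_by_bin(pts, spec)
    b = np.asarray(baselines)
    in_range = ((b >= spec.edges[0]) & (b < spec.edges[-1])).sum()
    assert tab["n_points"].sum() == in_range


def test_cluster_bootstrap_ci_brackets_mean():
    rng = np.random.default_rng(5)
    pts = _points(list(rng.normal(4, 2, 60)),
                  patient_id=[f"P{i % 6}" for i in range(60)])
    tab = change_by_bin(pts, BinSpec(min_observations=10),
                        ci_method="cluster_bootstrap", n_boot=200, rng=0)
    row = tab[tab["n_points"] == 60].iloc[0]
    assert row["ci_low"] < row["mean_change_db"] < row["ci_high"]


# --- range subsets and effect sizes ----------------------------------------

def test_range_subset_hand_statistics():
    r = range_subset_stats(_points([5.0, 11.0]), -25, -10).iloc[0]
    assert r["n_points"] == 2
    assert r["mean_change_db"] == pytest.approx(8.0)
    assert r["sd_change_db"] == pytest.approx(np.sqrt(18.0))  # ~4.243


def test_range_subset_single_point_flagged_degenerate():
    r = range_subset_stats(_points([5.0]), -25, -10).iloc[0]
    assert r["n_points"] == 1 and bool(r["degenerate"]) is True
    assert np.isnan(r["sd_change_db"])


def test_range_subset_arms_partition_whole():
    pts = _points([1.0, 2.0, 3.0, 4.0], arm=["cwi", "bariatric", "cwi", "bariatric"])
    whole = range_subset_stats(pts, -25, -10, "whole").iloc[0]
    arms = range_subset_stats(pts, -25, -10, "arm")
    assert arms["n_points"].sum() == whole["n_points"]


def test_range_subset_acetazolamide_split_within_cwi():
    pts = _points([1.0, 2.0, 3.0], arm=["cwi"] * 3, acz=[True, False, False])
    tab = range_subset_stats(pts, -25, -10, "arm_acetazolamide").set_index("group")
    assert tab.loc["cwi_acetazolamide", "n_points"] == 1
    assert tab.loc["cwi_no_acetazolamide", "n_points"] == 2
    assert tab.loc["cwi", "n_points"] == 3


def test_range_subset_invalid_range():
    with pytest.raises(ValueError):
        range_subset_stats(_points([1.0]), -10, -25)


@pytest.mark.parametrize(
    "mean,sd,expected",
    [(9.60, 6.99, 1.37), (8.77, 4.3, 2.04), (0.0, 5.0, 0.0)],
)
def test_effect_size_rounds_to_reported_values(mean, sd, expected):
    assert round_half_away(effect_size(mean, sd), 2) == expected


def test_effect_size_degenerate_dispersion():
    with pytest.raises(ValueError):
        effect_size(1.0, 0.0)


# --- location maps ---------------------------------------------------------

def test_md_stratum_partition():
    assert md_stratum(-1.0) == "ge_-2"
    assert md_stratum(-2.0) == "ge_-2"
    assert md_stratum(-4.0) == "-7_-2"
    assert md_stratum(-7.0) == "-7_-2"
    assert md_stratum(-7.01) == "le_-7"


def test_location_map_single_eye_equals_its_field(flat_model):
    rng = np.random.default_rng(2)
    s = np.clip(rng.uniform(15, 35, N_LOCATIONS), 0, 40)
    cohort = Cohort.from_exams([make_exam("P1", Eye.RIGHT, 0, s)])
    m = location_mean_map(cohort, flat_model, "all")
    td, _ = cohort.deviations(flat_model)
    assert np.allclose(m, td[0], equal_nan=True)


def test_location_map_two_eyes_average(flat_model):
    f = np.full(N_LOCATIONS, 20.0)
    g = np.full(N_LOCATIONS, 30.0)
    cohort = Cohort.from_exams([
        make_exam("P1", Eye.RIGHT, 0, f), make_exam("P1", Eye.LEFT, 0, g),
    ])
    m = location_mean_map(cohort, flat_model, "all")
    ok = ~np.isnan(m)
    assert np.allclose(m[ok], -5.0)  # mean of td -10 and 0


def test_location_map_empty_stratum_all_nan(flat_model):
    cohort = Cohort.from_exams([make_exam("P1", Eye.RIGHT, 0, np.full(N_LOCATIONS, 29.0))])
    m = location_mean_map(cohort, flat_model, "le_-7")
    assert np.isnan(m).all()


def test_location_map_eccentricity_gradient(model):
    """With an eccentricity-only defect model the outer ring is deepest."""
    cfg = dataclasses.replace(
        simulate.preset("iihwt_like"),
        ecc_weight=1.0, blindspot_weight=0.0, local_noise_weight=0.0,
        sigma0_db=0.5, sigma1_per_db=0.0, unreliable_prob=0.0, seed=42,
    )
    cohort, _ = simulate.generate(cfg, model)
    m = location_mean_map(cohort, model, "all")
    ecc = geometry.eccentricities()
    ok = ~np.isnan(m)
    inner = np.abs(m[ok & (ecc < 6)]).mean()
    outer = np.abs(m[ok & (ecc > 20)]).mean()
    assert outer > inner


def test_map_to_grid_layout():
    m = np.arange(N_LOCATIONS, dtype=float)
    grid = map_to_grid(m)
    assert grid.shape == (8, 9)  # y rows 21..-21, x cols -27..21
    assert grid.loc[21, -9] == 0.0  # first pattern location
    assert np.isnan(grid.loc[21, -27])  # corner not in pattern
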