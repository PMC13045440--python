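"""Binning, summaries, mixed models and classical tests."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mealscan.config import DietSpec, LightSchedule
from mealscan.errors import ContractError, DegenerateDataError
from mealscan.segmentation import segment
from mealscan.stats import (
    cycle_summary,
    fisher_one_tailed,
    fit_lmm,
    fold_change,
    hourly_bin,
    paired_t,
    percent_share,
    radial_export,
    raster_export,
    smooth_profile,
    sr_time_profile,
    zero_intake_hours,
)

from conftest import make_events

SCHED = LightSchedule()
DIET = DietSpec()


# ---------------------------------------------------------------------------
# hourly binning & zero-intake hours


def test_event_inside_one_bin():
    ev = make_events([(3 * 60 + 10, 3 * 60 + 12, 0.10)])
    hb = hourly_bin(ev, SCHED)
    assert hb.loc[hb["bin"] == 3, "intake_g"].iloc[0] == pytest.approx(0.10)
    assert hb.loc[hb["bin"] != 3, "intake_g"].sum() == 0.0
    assert len(hb) == 24


def test_no_events_gives_all_zero_matrix():
    hb = hourly_bin(make_events([]).iloc[:0], SCHED, days=[0])
    assert hb.empty  # no animals -> no rows


def test_boundary_event_split_pro_rata():
    # 06:59-07:01, 0.04 g -> 0.02 g in each adjacent bin
    ev = make_events([(59, 61, 0.04)])
    hb = hourly_bin(ev, SCHED)
    assert hb.loc[hb["bin"] == 0, "intake_g"].iloc[0] == pytest.approx(0.02)
    assert hb.loc[hb["bin"] == 1, "intake_g"].iloc[0] == pytest.approx(0.02)


def test_start_attribution_mode():
    ev = make_events([(59, 61, 0.04)])
    hb = hourly_bin(ev, SCHED, prorate=False)
    assert hb.loc[hb["bin"] == 0, "intake_g"].iloc[0] == pytest.approx(0.04)


def test_hourly_bins_conserve_mass(baseline_events):
    hb = hourly_bin(baseline_events, SCHED)
    assert hb["intake_g"].sum() == pytest.approx(baseline_events["intake_g"].sum(), abs=1e-9)


def test_zero_intake_hour_counting():
    # intake only in bins 0 and 13 -> 22 zero hours (11 light, 11 dark)
    ev = make_events([(10, 12, 0.10), (13 * 60 + 5, 13 * 60 + 7, 0.10)])
    z = zero_intake_hours(hourly_bin(ev, SCHED), SCHED)
    assert z.loc[0, ["zero_total", "zero_light", "zero_dark"]].tolist() == [22, 11, 11]


def test_all_zero_day_counts_24():
    ev = make_events([(10, 12, 0.10)])
    hb = hourly_bin(ev, SCHED, days=[0, 1])  # day 1 has no intake at all
    z = zero_intake_hours(hb, SCHED)
    day1 = z.loc[z["day"] == 1].iloc[0]
    assert (day1["zero_total"], day1["zero_light"], day1["zero_dark"]) == (24, 12, 12)


# ---------------------------------------------------------------------------
# cycle summary


def test_single_meal_leaves_interval_mean_absent():
    meals = segment(make_events([(0, 2, 0.10)]), DIET, SCHED)
    cs = cycle_summary(meals, SCHED)
    row = cs.iloc[0]
    assert row["n_meals"] == 1
    assert np.isnan(row["imi_min"]) and np.isnan(row["sr_min_per_01kcal"])


def test_cycle_summary_is_deterministic(paired_meals):
    a = cycle_summary(paired_meals, SCHED, n_days=3)
    b = cycle_summary(paired_meals.copy(), SCHED, n_days=3)
    pd.testing.assert_frame_equal(a, b)


def test_interval_assigned_to_preceding_meals_cycle():
    # meal at 17:40 (light) whose interval reaches into the dark cycle
    ev = make_events([(700, 702, 0.10), (725, 727, 0.10)])
    meals = segment(ev, DIET, SCHED)
    cs = cycle_summary(meals, SCHED)
    light = cs.loc[cs["cycle"] == "light"].iloc[0]
    assert light["imi_min"] == pytest.approx(23.0)


# ---------------------------------------------------------------------------
# linear mixed model


def _lmm_frame(shift, animal_sd, noise_sd, rng, n_animals=6, n_obs=25):
    rows = []
    for i in range(n_animals):
        a = rng.normal(0, animal_sd)
        for phase, mu in (("baseline", 30.0), ("kpc_d14", 30.0 + shift)):
            for _ in range(n_obs):
                rows.append((f"A{i}", phase, mu + a + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows, columns=["animal_id", "phase", "value"])


def test_lmm_exact_on_noiseless_shift():
    rng = np.random.default_rng(0)
    df = _lmm_frame(shift=12.0, animal_sd=0.0, noise_sd=0.0, rng=rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = fit_lmm(df)
    assert res.contrast == pytest.approx(12.0, abs=1e-8)
    assert res.emm["baseline"][0] == pytest.approx(30.0, abs=1e-8)
    assert res.emm["kpc_d14"][0] == pytest.approx(42.0, abs=1e-8)
    assert res.fallback  # zero between-animal variance degenerates to pooled fit


def test_lmm_recovers_shift_within_two_se():
    rng = np.random.default_rng(7)
    hits = 0
    reps = 30
    for _ in range(reps):
        df = _lmm_frame(shift=10.0, animal_sd=5.0, noise_sd=8.0, rng=rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_lmm(df)
        if abs(res.contrast - 10.0) <= 2 * res.se:
            hits += 1
    assert hits / reps >= 0.9


def test_lmm_requires_both_phases():
    df = _lmm_frame(0.0, 1.0, 1.0, np.random.default_rng(1))
    with pytest.raises(ContractError):
        fit_lmm(df.loc[df["phase"] == "baseline"])


# ---------------------------------------------------------------------------
# paired t


def test_paired_t_identical_pairs():
    res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == 0.0 and res.pvalue == 1.0


def test_paired_t_zero_variance_nonzero_shift_is_degenerate():
    with pytest.raises(DegenerateDataError):
        paired_t([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


def test_paired_t_matches_direct_formula():
    a = np.array([12.0, 9.5, 14.1, 10.0, 11.2])
    b = np.array([10.1, 8.0, 13.0, 9.7, 9.9])
    d = b - a
    t_direct = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
    res = paired_t(a, b)
    assert res.t == pytest.approx(t_direct, rel=1e-12)
    assert res.mean_difference == pytest.approx(d.mean())


def test_paired_t_requires_two_pairs():
    with pytest.raises(ContractError):
        paired_t([1.0], [2.0])


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_enum(table, direction):
    """Independent oracle: full hypergeometric enumeration over tables
    with the observed margins."""
    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

    def pmf(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    xs = range(a, hi + 1) if direction == "greater" else range(lo, a + 1)
    return sum(pmf(x) for x in xs)


def test_fisher_equal_rows_gives_p_one():
    assert fisher_one_tailed(((0, 24), (0, 24)), "greater").pvalue == pytest.approx(1.0)


def test_fisher_zero_intake_hours_contrast():
    # 12/24 affected hours vs 1/24: the published-style 2x2 comparison
    res = fisher_one_tailed(((12, 12), (1, 23)), "greater")
    assert res.pvalue < 0.0004
    assert res.pvalue == pytest.approx(fisher_enum(((12, 12), (1, 23)), "greater"), rel=1e-9)


def test_fisher_row_swap_reverses_tail():
    p_fwd = fisher_one_tailed(((12, 12), (1, 23)), "greater").pvalue
    p_swapped = fisher_one_tailed(((1, 23), (12, 12)), "less").pvalue
    assert p_fwd == pytest.approx(p_swapped, rel=1e-9)


def test_fisher_all_zero_table_is_contract_error():
    with pytest.raises(ContractError):
        fisher_one_tailed(((0, 0), (0, 0)))


@given(
    st.tuples(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
    ).filter(lambda t: sum(t) > 0),
    st.sampled_from(["greater", "less"]),
)
@settings(max_examples=150, derandomize=True, deadline=None)
def test_fisher_matches_enumeration(cells, direction):
    table = ((cells[0], cells[1]), (cells[2], cells[3]))
    res = fisher_one_tailed(table, direction)
    assert res.pvalue == pytest.approx(fisher_enum(table, direction), rel=1e-9, abs=1e-12)
    assert 0 < res.pvalue <= 1


# ---------------------------------------------------------------------------
# smoothing & profiles


def test_smooth_constant_series_unchanged():
    mean, _ = smooth_profile(np.full((3, 6), 5.0))
    assert mean == pytest.approx(np.full(5, 5.0))


def test_smooth_two_points_average_to_midpoint():
    mean, _ = smooth_profile(np.array([[0.0, 2.0]]))
    assert mean == pytest.approx([1.0])


def test_smooth_short_series_warns_and_passes_through():
    with pytest.warns(UserWarning):
        mean, _ = smooth_profile(np.array([[3.0]]))
    assert mean == pytest.approx([3.0])


def test_sr_profile_bins_by_preceding_meal(paired_meals):
    prof = sr_time_profile(paired_meals)
    assert set(prof["clock_bin_start"]).issubset(set(range(0, 24, 2)))
    # empty bins are absent rather than zero
    assert (prof["n"] > 0).all()


def test_cachectic_midday_satiety_ratio_surge(kpc_events, baseline_events):
    # zero-intake blocks concentrate in midday: the satiety ratio there
    # rises far above the early-light value, unlike at baseline
    prof_k = sr_time_profile(segment(kpc_events, DIET, SCHED))
    early = prof_k.loc[prof_k["clock_bin_start"] == 6, "sr_mean"]
    midday = prof_k.loc[prof_k["clock_bin_start"].isin([10, 12, 14]), "sr_mean"]
    assert len(early) and len(midday)
    assert midday.max() > 3 * early.iloc[0]


def test_sr_profile_single_bin():
    meals = segment(make_events([(0, 2, 0.10), (20, 22, 0.10)]), DIET, SCHED)
    prof = sr_time_profile(meals)
    assert len(prof) == 1 and prof.loc[0, "clock_bin_start"] == 6


# ---------------------------------------------------------------------------
# exports


def test_raster_one_row_per_meal():
    meals = segment(make_events([(0, 2, 0.10)]), DIET, SCHED)
    raster = raster_export(meals)
    assert len(raster) == 1
    assert raster.loc[0, "onset_clock_h"] == pytest.approx(6.0)


def test_radial_rows_sum_to_daily_mean(baseline_events):
    hb = hourly_bin(baseline_events, SCHED, diet=DIET)
    radial = radial_export(hb)
    daily_mean = hb.groupby(["animal_id", "day"])["intake_g"].sum().mean()
    # mean over animal-days equals the sum of per-hour means
    assert radial["intake_g"].sum() == pytest.approx(daily_mean, rel=1e-9)
    again = radial_export(hb)
    pd.testing.assert_frame_equal(radial, again)


# ---------------------------------------------------------------------------
# worked-example helpers


def test_percent_share_and_fold_change():
    assert percent_share(1.0, 4.0) == pytest.approx(25.0)
    assert fold_change(2.0, 7.0) == pytest.approx(3.5)
    with pytest.raises(ContractError):
        percent_share(1.0, 0.0)
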