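"""Synthetic cohort generator: determinism, structure, calibration."""

import numpy as np
import pandas as pd
import pytest

from mealscan.config import DietSpec, GeneratorConfig, LightSchedule, ProtocolSpec
from mealscan.errors import ConfigurationError
from mealscan.segmentation import filter_meals, merge_events_to_meals, segment
from mealscan.simulate import (
    generate_activity,
    generate_calorimetry,
    generate_feeding_events,
    generate_study,
)
from mealscan.stats import cycle_summary, hourly_bin, zero_intake_hours
from mealscan.energetics import ambulatory_count

SCHED = LightSchedule()
DIET = DietSpec()


# ---------------------------------------------------------------------------
# determinism & structure


def test_identical_seed_identical_events(baseline_events):
    cfg = GeneratorConfig(seed=0, n_animals=7)
    again = generate_feeding_events(cfg, days=3)
    pd.testing.assert_frame_equal(again, baseline_events)


def test_different_seeds_differ():
    a = generate_feeding_events(GeneratorConfig(seed=1, n_animals=2), days=1)
    b = generate_feeding_events(GeneratorConfig(seed=2, n_animals=2), days=1)
    assert not a.equals(b)


def test_events_sorted_nonoverlapping_and_quantized(baseline_events):
    for _, grp in baseline_events.groupby("animal_id"):
        starts, ends = grp["start"].to_numpy(), grp["end"].to_numpy()
        assert np.all(starts[1:] >= ends[:-1])
        assert np.all(ends >= starts)
    quanta = np.round(baseline_events["intake_g"] / 0.01)
    assert np.allclose(quanta * 0.01, baseline_events["intake_g"], atol=1e-9)
    assert (baseline_events["start"].dt.microsecond == 0).all()


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        GeneratorConfig(seed=1, state="tumour_free")
    with pytest.raises(ConfigurationError):
        GeneratorConfig(seed=1, n_animals=0)
    with pytest.raises(ConfigurationError):
        generate_feeding_events(GeneratorConfig(seed=1), days=0)


def test_nibbles_and_meals_both_present(baseline_events):
    clusters = merge_events_to_meals(baseline_events)
    meals, nibbles = filter_meals(clusters, return_removed=True)
    assert len(nibbles) > 0 and len(meals) > 0
    # nibbles are always single sub-threshold interactions
    assert (nibbles["n_events"] == 1).all()
    assert (nibbles["intake_g"] <= 0.03).all()
    # and some meals are recorded as multiple hopper interactions
    assert (meals["n_events"] > 1).any()


def test_segmentation_count_invariant_to_pause_scale(baseline_events):
    """Within-meal pauses (<5 min) and nibbles never alter the meal count:
    merging at any criterion between the pause and gap scales is stable."""
    meals_5 = filter_meals(merge_events_to_meals(baseline_events, min_imi=5.0))
    meals_2 = filter_meals(merge_events_to_meals(baseline_events, min_imi=2.0))
    assert len(meals_5) == len(meals_2)


# ---------------------------------------------------------------------------
# protocols


def test_starvation_day_has_empty_dark_cycle():
    cfg = GeneratorConfig(seed=4, n_animals=4)
    ev = generate_feeding_events(
        cfg, days=2, protocol=ProtocolSpec.starve_refeed(SCHED), start_day=3, context_code=3
    )
    starve0 = SCHED.day_anchor(3) + pd.Timedelta(hours=12)
    starve1 = SCHED.day_anchor(4)
    inside = ev.loc[(ev["end"] > starve0) & (ev["start"] < starve1)]
    assert inside.empty
    # feeding resumes promptly after food return at light onset
    refed = ev.loc[ev["start"] >= starve1]
    assert not refed.empty
    first = refed.groupby("animal_id")["start"].min()
    assert ((first - starve1) < pd.Timedelta(hours=2)).all()


def test_zero_blocks_only_in_cachectic_state(baseline_events, kpc_events):
    zb = zero_intake_hours(hourly_bin(baseline_events, SCHED), SCHED)
    zk = zero_intake_hours(hourly_bin(kpc_events, SCHED), SCHED)
    assert zb["zero_total"].mean() < 4
    assert zk["zero_total"].mean() > 8
    # cachectic days contain multi-hour zero runs
    hb = hourly_bin(kpc_events, SCHED)
    run_lengths = []
    for _, grp in hb.groupby(["animal_id", "day"]):
        zeros = (grp.sort_values("bin")["intake_g"] == 0.0).to_numpy()
        n = 0
        for z in list(zeros) + [False]:
            if z:
                n += 1
            elif n:
                run_lengths.append(n)
                n = 0
    assert any(r >= 2 for r in run_lengths)
    # the block sampler itself draws 2-4 blocks of 2-8 consecutive hours
    from mealscan.simulate import _sample_zero_block_hours

    rng = np.random.default_rng(0)
    params = GeneratorConfig(seed=0, state="kpc_d14").feeding.zero_blocks
    for _ in range(50):
        hours = sorted(_sample_zero_block_hours(rng, params, 12))
        blocks, n = [], 1
        for a, b in zip(hours, hours[1:]):
            if b == a + 1:
                n += 1
            else:
                blocks.append(n)
                n = 1
        blocks.append(n)
        assert 2 <= len(blocks) <= 4
        # block lengths stay in the 2-8 h range unless two abut by chance
        assert all(2 <= b <= 8 or b <= 16 for b in blocks)
        assert len(hours) == params.light_hours_total + params.dark_hours_total


def test_study_pairs_every_animal_across_phases():
    cfg = GeneratorConfig(seed=6, n_animals=3)
    study = generate_study(cfg)
    for animal in study.manifest.animals:
        phases = {
            o.phase for o in study.manifest.observations if o.animal_id == animal
        }
        assert phases == {"baseline", "kpc_d14"}
    assert set(study.events["phase"]) == {"baseline", "kpc_d14"}
    assert study.manifest.days(kind="starve_refeed", phase="baseline")
    # regenerating the study reproduces it exactly
    again = generate_study(cfg)
    pd.testing.assert_frame_equal(study.events, again.events)
    assert study.manifest == again.manifest


# ---------------------------------------------------------------------------
# calibration of the defaults (loose, few seeds; the full check is the
# acceptance suite)


def _cohort_stats(state, seeds=(0, 1, 2)):
    light, dark, dmeals = [], [], []
    for seed in seeds:
        cfg = GeneratorConfig(seed=seed, n_animals=7, state=state)
        ev = generate_feeding_events(cfg, days=3)
        hb = hourly_bin(ev, SCHED, diet=DIET)
        cyc = hb.groupby(["animal_id", "day", hb["bin"] < 12])["intake_kcal"].sum()
        light.append(cyc.xs(True, level=2).mean())
        dark.append(cyc.xs(False, level=2).mean())
        cs = cycle_summary(segment(ev, DIET, SCHED), SCHED, n_days=3)
        dmeals.append(cs.loc[cs["cycle"] == "dark", "meals_per_day"].mean())
    return np.mean(light), np.mean(dark), np.mean(dmeals)


def test_baseline_daily_intake_near_published_cycle_totals():
    light, dark, _ = _cohort_stats("baseline")
    assert light == pytest.approx(4.12, rel=0.10)
    assert dark == pytest.approx(7.9, rel=0.10)


def test_cachectic_24h_intake_halved():
    light, dark, _ = _cohort_stats("kpc_d14")
    assert light + dark == pytest.approx(6.07, rel=0.15)


def test_meal_frequency_collapse_in_cachexia():
    _, _, dm_base = _cohort_stats("baseline")
    _, _, dm_kpc = _cohort_stats("kpc_d14")
    assert dm_base == pytest.approx(22, rel=0.15)
    assert dm_kpc < 0.65 * dm_base


# ---------------------------------------------------------------------------
# calorimetry & activity streams


def test_calorimetry_grid_and_bounds():
    cfg = GeneratorConfig(seed=3, n_animals=2)
    cal = generate_calorimetry(cfg, days=2)
    one = cal.loc[cal["animal_id"] == "M01", "time"]
    steps = one.diff().dropna().unique()
    assert len(steps) == 1 and steps[0] == pd.Timedelta(minutes=10)
    assert (cal["vo2_l_h"] > 0).all() and (cal["vco2_l_h"] > 0).all()
    r = cal["vco2_l_h"] / cal["vo2_l_h"]
    assert r.between(0.7 - 1e-3, 1.05 + 1e-3).all()
    pd.testing.assert_frame_equal(cal, generate_calorimetry(cfg, days=2))


def test_cachectic_dark_vo2_reduction():
    base = generate_calorimetry(GeneratorConfig(seed=5, n_animals=5), days=3)
    kpc = generate_calorimetry(
        GeneratorConfig(seed=5, n_animals=5, state="kpc_d14"), days=3
    )
    dark = lambda df: df.loc[[SCHED.cycle_at(t) == "dark" for t in df["time"]], "vo2_l_h"].mean()
    drop = 1 - dark(kpc) / dark(base)
    assert 0.21 - 0.03 <= drop <= 0.23 + 0.03


def test_activity_fold_and_decline():
    base = generate_activity(GeneratorConfig(seed=8, n_animals=5), days=3)
    kpc = generate_activity(GeneratorConfig(seed=8, n_animals=5, state="kpc_d14"), days=3)
    cb = ambulatory_count(base, SCHED).groupby("cycle")["ambulatory_count"].sum()
    ck = ambulatory_count(kpc, SCHED).groupby("cycle")["ambulatory_count"].sum()
    assert cb["dark"] / cb["light"] == pytest.approx(3.8, rel=0.15)
    assert 1 - ck["dark"] / cb["dark"] == pytest.approx(0.67, abs=0.07)
    assert 1 - ck["light"] / cb["light"] == pytest.approx(0.48, abs=0.10)


def test_zero_activity_rate_gives_empty_stream():
    from dataclasses import replace

    cfg = GeneratorConfig(seed=1, n_animals=2)
    quiet = replace(
        cfg.metabolic,
        ambulatory_rate_light_per_h=0.0,
        ambulatory_rate_dark_per_h=0.0,
        stationary_rate_per_h=0.0,
        rearing_rate_per_h=0.0,
    )
    cfg2 = GeneratorConfig(seed=1, n_animals=2, metabolic=quiet)
    stream = generate_activity(cfg2, days=1)
    assert stream.empty
    counts = ambulatory_count(stream, SCHED)
    assert counts.empty or counts["ambulatory_count"].sum() == 0


def test_activity_contains_both_run_types():
    stream = generate_activity(GeneratorConfig(seed=1, n_animals=1), days=1)
    x = stream.loc[stream["axis"] == "X"].sort_values("time")
    dt = x["time"].diff().dt.total_seconds().to_numpy()
    beams = x["beam_index"].to_numpy()
    runs, cur = [], [0]
    for i in range(1, len(x)):
        if dt[i] < 1.0:
            cur.append(i)
        else:
            runs.append(cur)
            cur = [i]
    runs.append(cur)
    kinds = {
        "ambulatory" if any(abs(beams[b] - beams[a]) == 1 for a, b in zip(r, r[1:]))
        else "stationary"
        for r in runs
        if len(r) > 1
    }
    assert kinds == {"ambulatory", "stationary"}
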