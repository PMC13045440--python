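"""Seeded synthetic CLAMS cohorts: feeding events, gas exchange, activity.

The feeding model is an inhomogeneous renewal process per 12-h cycle:
meal onsets follow exponential waiting times (floored at the 5-min meal
criterion so generated meals never re-merge) whose hourly rate follows a
diurnal hazard shape; the base rate is solved per day so the *expected*
per-cycle meal count equals the calibrated target even when parts of the
cycle are unavailable (zero-intake blocks, food removal).  Meal sizes and
durations are lower-truncated normals whose location is solved so the
truncated mean hits the calibrated value.  A fraction of meals is split
into two hopper interactions separated by a sub-5-min pause, and
sub-threshold "nibbles" (<= 0.03 g) are sprinkled between meals; both are
placed so they can never alter downstream segmentation (pauses < 5 min,
nibbles > 5 min from any other event).

The cachectic state adds clock-hour-aligned zero-intake blocks on
spontaneous days and scales gas exchange and ambulation down by the
calibrated state multipliers.  Evoked protocol days (starve-refeed,
ghrelin/vehicle) apply transient hazard/size boosts after the cue.

Intakes are quantized to the balance resolution (0.01 g); event times to
1 s; activity beam breaks to 1 ms.  Identical configurations and seeds
yield byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from . import calibration
from .config import (
    STREAM_ACTIVITY,
    STREAM_CALORIMETRY,
    STREAM_FEEDING,
    STREAM_TRAITS,
    GeneratorConfig,
    LightSchedule,
    MealTimingParams,
    ProtocolSpec,
    subseed_rng,
)
from .errors import ConfigurationError
from .io import ObservationDay, StudyManifest

__all__ = [
    "generate_feeding_events",
    "generate_calorimetry",
    "generate_activity",
    "generate_study",
    "StudyData",
]

#: minimum separation between generated meals (> the 5-min criterion, with
#: headroom for 1-s timestamp rounding); shared with the boost calibration
MEAL_SEPARATION_MIN = calibration.MEAL_SEPARATION_MIN
#: exclusion radius of nibbles around any other event
NIBBLE_EXCLUSION_MIN = 5.1

# ---------------------------------------------------------------------------
# small samplers


class _TruncNormSampler:
    """Lower-truncated normal with exact target mean (location pre-solved)."""

    def __init__(self):
        self._locs: Dict[Tuple[float, float, float], float] = {}

    def draw(self, rng: np.random.Generator, mean: float, sd: float, lower: float) -> float:
        key = (mean, sd, lower)
        loc = self._locs.get(key)
        if loc is None:
            loc = calibration.truncnorm_loc(mean, sd, lower) if sd > 0 else mean
            self._locs[key] = loc
        if sd <= 0:
            return mean
        for _ in range(1000):
            x = rng.normal(loc, sd)
            if x >= lower:
                return x
        return lower  # pragma: no cover - acceptance prob is ~1


_TRUNC = _TruncNormSampler()


def _quantize(grams: float, quantum: float) -> float:
    return round(round(grams / quantum) * quantum, 10)


def _animal_traits(config: GeneratorConfig, a_idx: int) -> Tuple[float, float]:
    """Persistent individual multipliers for meal size and inter-meal gap.

    The size trait is lognormal with mean 1 (cohort intake unbiased); the
    gap trait is lognormal with median 1, splitting its convexity bias
    evenly between cohort meal counts and intervals; the residual count
    inflation is absorbed by the sampler-bias factor in the calibration
    module."""
    rng = subseed_rng(config.seed, a_idx, STREAM_TRAITS)
    out = []
    for cv, centering in (
        (config.feeding.between_animal_size_cv, "mean"),
        (config.feeding.between_animal_gap_cv, "median"),
    ):
        if cv <= 0:
            out.append(1.0)
            rng.normal()  # keep the stream layout stable
            continue
        sigma = np.sqrt(np.log1p(cv * cv))
        mu = -0.5 * sigma * sigma if centering == "mean" else 0.0
        out.append(float(np.exp(rng.normal(mu, sigma))))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# per-day scaffolding


def _sample_zero_block_hours(rng: np.random.Generator, params, light_hours: int) -> set:
    """Clock-hour offsets (0-23 within the day) covered by zero-intake blocks."""
    hours: set = set()
    for total, (w0, w1), base in (
        (params.light_hours_total, params.light_window, 0),
        (params.dark_hours_total, params.dark_window, light_hours),
    ):
        if total <= 0:
            continue
        # partition the cycle's block hours into 1-2 blocks within [min,max]
        if total >= 2 * params.min_len and rng.random() < 0.5:
            lo = max(params.min_len, total - params.max_len)
            hi = min(params.max_len, total - params.min_len)
            first = int(rng.integers(lo, hi + 1))
            lengths = [first, total - first]
        else:
            lengths = [min(total, params.max_len)]
            if total > params.max_len:  # pragma: no cover - not with defaults
                lengths.append(total - params.max_len)
        # place without overlap inside the cycle window, 100 attempts then pack
        placed: List[Tuple[int, int]] = []
        for _ in range(100):
            placed = []
            ok = True
            for ln in lengths:
                start = int(rng.integers(w0, w1 - ln + 1))
                if any(start < e and start + ln > s for s, e in placed):
                    ok = False
                    break
                placed.append((start, start + ln))
            if ok:
                break
        if not ok:  # fallback: deterministic packing from the window start
            placed, cursor = [], w0
            for ln in lengths:
                placed.append((cursor, cursor + ln))
                cursor += ln + 1
        for s, e in placed:
            hours.update(range(base + s, base + e))
    return hours


def _free_spans(forbidden_hours: set, h0: int, h1: int) -> List[Tuple[float, float]]:
    """Maximal free [start_min, end_min) spans between day-hours h0..h1."""
    spans = []
    run_start = None
    for h in range(h0, h1 + 1):
        blocked = h in forbidden_hours or h == h1
        if not blocked and run_start is None:
            run_start = h
        elif blocked and run_start is not None:
            spans.append((run_start * 60.0, h * 60.0))
            run_start = None
    return spans


@dataclass
class _DayPlan:
    """Resolved sampling plan for one animal-day."""

    forbidden_hours: set
    boosts: Tuple[Tuple[float, float, float, float], ...]  # (t0, t1, hazard, size)
    base_gap: Dict[str, float]


def _day_plan(config: GeneratorConfig, protocol: ProtocolSpec, day_in_protocol: int) -> _DayPlan:
    """Forbidden hours and boost windows for one protocol day (blocks excluded)."""
    feeding = config.feeding
    light_h = int(round(config.schedule.light_hours))
    forbidden: set = set()
    boosts: List[Tuple[float, float, float, float]] = []

    if protocol.kind == "starve_refeed":
        if day_in_protocol == 0:
            # food withheld over the dark cycle
            forbidden.update(range(light_h, 24))
        else:
            b = feeding.refeed_boost
            boosts.append((0.0, b.duration_h * 60.0, b.hazard_mult, b.size_mult))
            if b.tail_duration_h > 0:
                boosts.append(
                    (b.duration_h * 60.0, (b.duration_h + b.tail_duration_h) * 60.0,
                     b.tail_hazard_mult, 1.0)
                )
    elif protocol.kind == "ghrelin":
        b = feeding.ghrelin_boost
        inj = protocol.injection_time
        on = config.schedule.light_on
        offset_min = ((inj.hour * 60 + inj.minute) - (on.hour * 60 + on.minute)) % (24 * 60)
        boosts.append((float(offset_min), offset_min + b.duration_h * 60.0,
                       b.hazard_mult, b.size_mult))
    # vehicle / dark_onset / spontaneous: no manipulation of the process
    return _DayPlan(forbidden_hours=forbidden, boosts=tuple(boosts), base_gap={})


def _boost_at(boosts, t_min: float) -> Tuple[float, float]:
    for t0, t1, hm, sm in boosts:
        if t0 <= t_min < t1:
            return hm, sm
    return 1.0, 1.0


def _hour_shapes(config: GeneratorConfig) -> Dict[str, np.ndarray]:
    f = config.feeding
    return {
        "light": calibration.normalized_shape(f.hazard_shape_light),
        "dark": calibration.normalized_shape(f.hazard_shape_dark),
    }


# ---------------------------------------------------------------------------
# feeding


def generate_feeding_events(
    config: GeneratorConfig,
    days: int,
    protocol: ProtocolSpec = ProtocolSpec.spontaneous(),
    start_day: int = 0,
    context_code: int = 0,
) -> pd.DataFrame:
    """Per-animal hopper-interaction logs over ``days`` observation days.

    For the ``starve_refeed`` protocol, day 0 is the starvation day (no
    events over the dark cycle) and day 1 the refeed day; other protocols
    act on every generated day.  ``start_day`` offsets the calendar;
    ``context_code`` separates random streams of repeated calls in a study.
    """
    if days < 1:
        raise ConfigurationError("days must be >= 1")
    schedule = config.schedule
    light_h = int(round(schedule.light_hours))
    shapes = _hour_shapes(config)
    feeding = config.feeding
    density = config.diet_energy_density
    size_lower_kcal = None  # per-cycle lower bounds resolved below

    rows: List[tuple] = []
    for a_idx, animal in enumerate(config.animal_ids()):
        # persistent individual traits: the same virtual animal keeps its
        # size/interval tendency across phases and protocols of a study
        size_f, gap_f = _animal_traits(config, a_idx)
        rng = subseed_rng(config.seed, a_idx, STREAM_FEEDING, context_code)
        for d in range(days):
            day = start_day + d
            plan = _day_plan(config, protocol, d)
            forbidden = set(plan.forbidden_hours)
            if (
                feeding.zero_blocks is not None
                and protocol.kind in ("spontaneous", "dark_onset")
            ):
                forbidden |= _sample_zero_block_hours(rng, feeding.zero_blocks, light_h)

            anchor = schedule.day_anchor(day)
            day_events: List[Tuple[float, float, float]] = []  # (start_min, end_min, g)

            for cycle, h0, h1 in (("light", 0, light_h), ("dark", light_h, 24)):
                timing: MealTimingParams = getattr(feeding, cycle)
                shape = shapes[cycle]
                free_min = np.array(
                    [0.0 if (h0 + i) in forbidden else 60.0 for i in range(h1 - h0)]
                )
                if free_min.sum() <= 0 or timing.meals_per_cycle <= 0:
                    continue
                base_gap = gap_f * calibration.solve_base_gap(
                    timing.meals_per_cycle / calibration.SAMPLER_COUNT_BIAS,
                    timing.duration_mean_min, shape, free_min,
                )
                def _gap_mean_at(t_min: float) -> float:
                    hour_in_cycle = min(int(t_min // 60.0) - h0, len(shape) - 1)
                    hazard_mult, _ = _boost_at(plan.boosts, t_min)
                    gap_eff = base_gap / (shape[hour_in_cycle] * hazard_mult)
                    return max(gap_eff - MEAL_SEPARATION_MIN, 0.05)

                spans = _free_spans(forbidden, h0, h1)
                for span_start, span_end in spans:
                    t = span_start
                    while True:
                        # inhomogeneous renewal wait: the 5-min floor in real
                        # time, then an Exp(1) budget consumed piecewise at
                        # the local hourly rate (time rescaling), so rate
                        # changes during the wait are handled exactly
                        p = t + MEAL_SEPARATION_MIN
                        budget = rng.exponential(1.0)
                        while True:
                            m = _gap_mean_at(min(p, span_end - 1e-9))
                            edge = np.floor(p / 60.0 + 1.0) * 60.0
                            step = budget * m
                            if p + step <= edge or p >= span_end:
                                p += step
                                break
                            budget -= (edge - p) / m
                            p = edge
                        t = p
                        if t >= span_end - timing.duration_min_min:
                            break
                        hazard_mult, size_mult = _boost_at(plan.boosts, t)
                        dur = _TRUNC.draw(
                            rng, timing.duration_mean_min, timing.duration_sd_min,
                            timing.duration_min_min,
                        )
                        dur = min(dur, span_end - t)
                        size_kcal = _TRUNC.draw(
                            rng,
                            timing.size_mean_kcal * size_mult * size_f,
                            timing.size_sd_kcal * size_mult * size_f,
                            timing.size_min_g * density,
                        )
                        grams = max(
                            _quantize(size_kcal / density, config.scale_resolution),
                            timing.size_min_g,
                        )
                        day_events.extend(
                            _emit_meal(rng, feeding, t, dur, grams, config.scale_resolution)
                        )
                        t = t + dur

            # sub-threshold nibbles, kept > 5 min away from everything
            day_events.sort()
            free_spans_all = _free_spans(forbidden, 0, 24)
            day_events = _add_nibbles(
                rng, feeding, day_events, free_spans_all
            )

            for s_min, e_min, grams in day_events:
                start = anchor + pd.Timedelta(seconds=round(s_min * 60.0))
                end = anchor + pd.Timedelta(seconds=round(e_min * 60.0))
                rows.append((animal, start, end, grams))

    df = pd.DataFrame(rows, columns=["animal_id", "start", "end", "intake_g"])
    return df.sort_values(["animal_id", "start"], kind="mergesort").reset_index(drop=True)


def _emit_meal(
    rng: np.random.Generator,
    feeding,
    t: float,
    dur: float,
    grams: float,
    quantum: float,
) -> List[Tuple[float, float, float]]:
    """One meal as 1-2 hopper interactions (within-meal pause < 5 min)."""
    quanta = int(round(grams / quantum))
    if (
        quanta >= 2
        and dur >= 1.0
        and rng.random() < feeding.split_probability
    ):
        pause_hi = min(feeding.pause_max_min, 0.4 * dur)
        if pause_hi > feeding.pause_min_min:
            pause = rng.uniform(feeding.pause_min_min, pause_hi)
            eat = dur - pause
            u = rng.uniform(0.3, 0.7)
            e1 = max(eat * u, 1.0 / 60.0)
            n1 = int(np.clip(round(quanta * u), 1, quanta - 1))
            g1 = round(n1 * quantum, 10)
            g2 = round(grams - g1, 10)
            return [
                (t, t + e1, g1),
                (t + e1 + pause, t + dur, g2),
            ]
    return [(t, t + dur, grams)]


def _add_nibbles(
    rng: np.random.Generator,
    feeding,
    day_events: List[Tuple[float, float, float]],
    free_spans: List[Tuple[float, float]],
) -> List[Tuple[float, float, float]]:
    if feeding.nibble_rate_per_h <= 0 or not free_spans:
        return day_events
    # keep nibbles clear of the day edges too, so events of adjacent days
    # can never fall within the 5-min criterion of each other
    day_len = 24 * 60.0
    free_spans = [
        (max(s, NIBBLE_EXCLUSION_MIN), min(e, day_len - NIBBLE_EXCLUSION_MIN))
        for s, e in free_spans
    ]
    free_spans = [(s, e) for s, e in free_spans if e > s]
    if not free_spans:
        return day_events
    free_total_h = sum(e - s for s, e in free_spans) / 60.0
    n = rng.poisson(feeding.nibble_rate_per_h * free_total_h)
    events = list(day_events)
    widths = np.array([e - s for s, e in free_spans])
    cum = np.cumsum(widths)
    for _ in range(n):
        for _attempt in range(200):
            u = rng.uniform(0, cum[-1])
            k = int(np.searchsorted(cum, u, side="right"))
            t = free_spans[k][0] + (u - (cum[k - 1] if k else 0.0))
            dur = rng.uniform(5.0, 30.0) / 60.0
            if t + dur > free_spans[k][1]:
                continue
            if all(
                t >= e + NIBBLE_EXCLUSION_MIN or t + dur <= s - NIBBLE_EXCLUSION_MIN
                for s, e, _ in events
            ):
                grams = float(
                    rng.choice(feeding.nibble_grams, p=feeding.nibble_weights)
                )
                events.append((t, t + dur, grams))
                break
    events.sort()
    return events


# ---------------------------------------------------------------------------
# calorimetry


def generate_calorimetry(
    config: GeneratorConfig,
    days: int,
    start_day: int = 0,
    context_code: int = 0,
) -> pd.DataFrame:
    """Gas-exchange scans on a regular grid (VO2/VCO2 in L/h).

    VO2 follows the per-cycle level with AR(1) noise; RER follows the
    per-cycle setpoint with a transient feeding-coupled elevation in the
    first two dark hours (the nocturnal carbohydrate-oxidation excursion).
    """
    if days < 1:
        raise ConfigurationError("days must be >= 1")
    met = config.metabolic
    schedule = config.schedule
    step_min = met.scan_interval_min
    n_per_day = int(round(24 * 60 / step_min))
    light_h = schedule.light_hours

    rows = []
    for a_idx, animal in enumerate(config.animal_ids()):
        rng = subseed_rng(config.seed, a_idx, STREAM_CALORIMETRY, context_code)
        vo2_noise = 0.0
        rer_noise = 0.0
        phi = 0.6
        for d in range(days):
            anchor = schedule.day_anchor(start_day + d)
            for i in range(n_per_day):
                t_min = i * step_min
                hour = t_min / 60.0
                in_light = hour < light_h
                vo2_level = met.vo2_light_l_h if in_light else met.vo2_dark_l_h
                rer_level = met.rer_light if in_light else met.rer_dark
                if light_h <= hour < light_h + 2.0:
                    rer_level = rer_level + met.rer_feeding_excursion
                vo2_noise = phi * vo2_noise + rng.normal(0.0, met.vo2_noise_sd)
                rer_noise = phi * rer_noise + rng.normal(0.0, met.rer_noise_sd)
                vo2 = max(vo2_level + vo2_noise, 0.005)
                rer_val = float(np.clip(rer_level + rer_noise, 0.7, 1.05))
                ts = anchor + pd.Timedelta(seconds=round(t_min * 60))
                rows.append((animal, ts, vo2, rer_val * vo2))
    df = pd.DataFrame(rows, columns=["animal_id", "time", "vo2_l_h", "vco2_l_h"])
    # serialize at the file dialect's precision so in-memory and round-tripped
    # data agree exactly
    df["vo2_l_h"] = df["vo2_l_h"].round(4)
    df["vco2_l_h"] = df["vco2_l_h"].round(4)
    return df


# ---------------------------------------------------------------------------
# activity


def generate_activity(
    config: GeneratorConfig,
    days: int,
    start_day: int = 0,
    context_code: int = 0,
) -> pd.DataFrame:
    """Infrared beam-break streams with ambulatory runs and stationary bouts.

    Ambulatory runs traverse >= 2 adjacent X beams at sub-second spacing;
    stationary bouts repeat a single beam; rears break Z beams.  Bouts are
    placed with a >= 2-s buffer so downstream run segmentation (1-s
    quiescence gap) recovers the generated counts exactly.
    """
    if days < 1:
        raise ConfigurationError("days must be >= 1")
    met = config.metabolic
    schedule = config.schedule
    light_h = schedule.light_hours

    rows = []
    for a_idx, animal in enumerate(config.animal_ids()):
        rng = subseed_rng(config.seed, a_idx, STREAM_ACTIVITY, context_code)
        for d in range(days):
            anchor = schedule.day_anchor(start_day + d)
            occupied: List[Tuple[float, float]] = []  # seconds within the day

            def _place(rng, span_s: float, cycle_start_h: float, cycle_len_h: float):
                lo = cycle_start_h * 3600.0
                hi = (cycle_start_h + cycle_len_h) * 3600.0 - span_s
                for _ in range(100):
                    t0 = rng.uniform(lo, hi)
                    if all(t0 >= e + 2.0 or t0 + span_s <= s - 2.0 for s, e in occupied):
                        occupied.append((t0, t0 + span_s))
                        return t0
                return None

            for cycle_start, cycle_len, amb_rate in (
                (0.0, light_h, met.ambulatory_rate_light_per_h),
                (light_h, 24.0 - light_h, met.ambulatory_rate_dark_per_h),
            ):
                n_amb = rng.poisson(amb_rate * cycle_len)
                n_stat = rng.poisson(met.stationary_rate_per_h * cycle_len)
                n_rear = rng.poisson(met.rearing_rate_per_h * cycle_len)
                for _ in range(n_amb):
                    steps = int(rng.integers(2, 7))
                    t0 = _place(rng, 0.3 * (steps - 1) + 0.1, cycle_start, cycle_len)
                    if t0 is None:
                        continue
                    beam = int(rng.integers(0, met.n_beams))
                    direction = 1 if rng.random() < 0.5 else -1
                    for k in range(steps):
                        rows.append(
                            (animal, anchor + pd.Timedelta(milliseconds=round((t0 + 0.3 * k) * 1000)),
                             "X", beam)
                        )
                        nxt = beam + direction
                        if nxt < 0 or nxt >= met.n_beams:
                            direction = -direction
                            nxt = beam + direction
                        beam = nxt
                for _ in range(n_stat):
                    reps = int(rng.integers(2, 6))
                    t0 = _place(rng, 0.4 * (reps - 1) + 0.1, cycle_start, cycle_len)
                    if t0 is None:
                        continue
                    beam = int(rng.integers(0, met.n_beams))
                    for k in range(reps):
                        rows.append(
                            (animal, anchor + pd.Timedelta(milliseconds=round((t0 + 0.4 * k) * 1000)),
                             "X", beam)
                        )
                for _ in range(n_rear):
                    t0 = _place(rng, 0.1, cycle_start, cycle_len)
                    if t0 is None:
                        continue
                    rows.append(
                        (animal, anchor + pd.Timedelta(milliseconds=round(t0 * 1000)),
                         "Z", int(rng.integers(0, met.n_beams)))
                    )
    df = pd.DataFrame(rows, columns=["animal_id", "time", "axis", "beam_index"])
    return df.sort_values(["animal_id", "time"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# paired study


@dataclass
class StudyData:
    """Full paired dataset: each animal observed healthy then cachectic."""

    manifest: StudyManifest
    events: pd.DataFrame        # with 'phase' column
    calorimetry: pd.DataFrame   # with 'phase' column (spontaneous days)
    activity: pd.DataFrame      # with 'phase' column (spontaneous days)


#: study layout: (phase, start_day, protocol factory, n_days)
STUDY_LAYOUT = (
    ("baseline", 0, "spontaneous", 3),
    ("baseline", 3, "starve_refeed", 2),
    ("baseline", 5, "ghrelin", 1),
    ("baseline", 6, "vehicle", 1),
    ("kpc_d14", 13, "spontaneous", 3),
    ("kpc_d14", 16, "starve_refeed", 2),
    ("kpc_d14", 18, "ghrelin", 1),
    ("kpc_d14", 19, "vehicle", 1),
)


def _protocol_for(kind: str, schedule: LightSchedule) -> ProtocolSpec:
    if kind == "spontaneous":
        return ProtocolSpec.spontaneous()
    if kind == "starve_refeed":
        return ProtocolSpec.starve_refeed(schedule)
    if kind == "ghrelin":
        return ProtocolSpec.ghrelin()
    if kind == "vehicle":
        return ProtocolSpec.vehicle()
    raise ConfigurationError(kind)  # pragma: no cover


def generate_study(config: GeneratorConfig) -> StudyData:
    """Within-animal paired design: 3 spontaneous baseline days, evoked
    protocol days, then the same animals in the cachectic day-14 state.

    The light schedule, diet and protocol windows are recorded in the
    returned manifest; events/calorimetry/activity carry a ``phase``
    column.  Fixed seed implies identical output.
    """
    schedule = config.schedule
    animals = config.animal_ids()
    observations: List[ObservationDay] = []
    event_parts, cal_parts, act_parts = [], [], []

    for phase, start_day, kind, n_days in STUDY_LAYOUT:
        cfg = config.with_state(phase)
        proto = _protocol_for(kind, schedule)
        ev = generate_feeding_events(
            cfg, days=n_days, protocol=proto, start_day=start_day, context_code=start_day
        )
        ev["phase"] = phase
        event_parts.append(ev)
        if kind == "spontaneous":
            cal = generate_calorimetry(cfg, days=n_days, start_day=start_day,
                                       context_code=start_day)
            cal["phase"] = phase
            cal_parts.append(cal)
            act = generate_activity(cfg, days=n_days, start_day=start_day,
                                    context_code=start_day)
            act["phase"] = phase
            act_parts.append(act)
        for animal in animals:
            for d in range(n_days):
                observations.append(ObservationDay(animal, start_day + d, phase, proto))

    manifest = StudyManifest(
        animals=animals,
        schedule=schedule,
        diet_energy_density=config.diet_energy_density,
        observations=observations,
    )
    return StudyData(
        manifest=manifest,
        events=pd.concat(event_parts, ignore_index=True),
        calorimetry=pd.concat(cal_parts, ignore_index=True),
        activity=pd.concat(act_parts, ignore_index=True),
    )
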