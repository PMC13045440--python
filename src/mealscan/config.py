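"""Study configuration: light schedule, diet, protocols and the stochastic
parameters of the synthetic CLAMS cohort generator.

The generator emulates singly housed mice in a metabolic cage under a
12 h:12 h photoperiod (lights on 06:00, off 18:00).  Two physiological
states are modelled:

``baseline``
    healthy adult mice: ~12 kcal/day, strongly nocturnal feeding, dense
    short meals in the dark, a dawn feeding peak with a mid-light trough.

``kpc_d14``
    cachectic mice 14 days after intraperitoneal injection of syngeneic
    KPC pancreatic adenocarcinoma cells: ~50% lower intake, far fewer
    meals, prolonged intermeal intervals and multi-hour blocks with no
    feeding at all, reduced VO2, RER and ambulation.

Default parameters are calibrated against published cohort statistics for
the two states (daily light/dark intake, per-cycle meal counts, intermeal
intervals, meal sizes and durations, zero-intake hours, activity and gas
exchange contrasts); see :mod:`mealscan.calibration` and docs/methods.md
for how mutually over-determined published summaries are reconciled.

Seeding rule
------------
A single master seed drives everything.  Each per-animal, per-stream
random generator is built as
``numpy.random.default_rng(SeedSequence((master_seed, animal_index,
stream_code, context_code)))`` where ``stream_code`` identifies the data
stream (feeding=1, calorimetry=2, activity=3) and ``context_code`` the
phase/protocol context, so any sub-stream can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, time
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Reference date used when the generator lays events on a calendar; day 0
#: begins at light onset of this date.  Purely cosmetic — all analyses are
#: clock-relative.
EPOCH_DATE = datetime(2024, 1, 1)

CYCLES = ("light", "dark")
STATES = ("baseline", "kpc_d14")
PROTOCOL_KINDS = ("spontaneous", "dark_onset", "starve_refeed", "ghrelin", "vehicle")

# stream codes for the documented seed-splitting rule
STREAM_FEEDING = 1
STREAM_CALORIMETRY = 2
STREAM_ACTIVITY = 3
STREAM_TRAITS = 4  # per-animal traits, shared across phases/protocols

# default between-animal trait CVs (shared with the calibration module,
# which corrects meal sizes for the small count bias the gap trait induces)
TRAIT_SIZE_CV = 0.15
TRAIT_GAP_CV = 0.20


def subseed_rng(seed: int, *codes: int) -> np.random.Generator:
    """Derive a stream generator from the master seed by the documented rule."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(c) for c in codes)))


@dataclass(frozen=True)
class LightSchedule:
    """12 h:12 h housing photoperiod, clock-local."""

    light_on: time = time(6, 0)
    light_off: time = time(18, 0)

    def __post_init__(self):
        if self.light_on == self.light_off:
            raise ConfigurationError("light_on and light_off must differ")

    @property
    def light_hours(self) -> float:
        delta = (_minutes(self.light_off) - _minutes(self.light_on)) % (24 * 60)
        return delta / 60.0

    @property
    def dark_hours(self) -> float:
        return 24.0 - self.light_hours

    def cycle_at(self, ts) -> str:
        """Cycle ('light'/'dark') containing a clock time or timestamp."""
        t = ts.time() if hasattr(ts, "time") else ts
        m, on, off = _minutes(t), _minutes(self.light_on), _minutes(self.light_off)
        if on < off:
            return "light" if on <= m < off else "dark"
        return "light" if (m >= on or m < off) else "dark"

    def day_anchor(self, day_index: int) -> pd.Timestamp:
        """Timestamp of light onset of observation day ``day_index``."""
        return pd.Timestamp(EPOCH_DATE) + pd.Timedelta(days=int(day_index)) + pd.Timedelta(
            hours=self.light_on.hour, minutes=self.light_on.minute
        )

    def day_index(self, ts) -> int:
        """Observation day containing ``ts`` (days begin at light onset)."""
        delta = pd.Timestamp(ts) - self.day_anchor(0)
        return int(np.floor(delta / pd.Timedelta(days=1)))


def _minutes(t: time) -> int:
    return t.hour * 60 + t.minute


@dataclass(frozen=True)
class DietSpec:
    """Diet energy density (kcal metabolizable energy per g of chow).

    The default of 3.0 kcal/g is typical for standard rodent chow and makes
    a ~12 kcal/day healthy intake correspond to ~4 g/day.
    """

    energy_density: float = 3.0

    def __post_init__(self):
        if not self.energy_density > 0:
            raise ConfigurationError("diet energy density must be positive")


@dataclass(frozen=True)
class ProtocolSpec:
    """An evoked-feeding protocol day.

    kind
        'spontaneous' (no manipulation), 'dark_onset' (analysis-only window at
        lights off), 'starve_refeed' (food removed over one full dark cycle,
        returned at light onset), 'ghrelin'/'vehicle' (i.p. injection in the
        light cycle, intake read over a post-injection window).
    """

    kind: str = "spontaneous"
    food_removed: Optional[Tuple[time, time]] = None
    injection_time: Optional[time] = None
    response_window_h: float = 4.0

    def __post_init__(self):
        if self.kind not in PROTOCOL_KINDS:
            raise ConfigurationError(f"unknown protocol kind {self.kind!r}")
        if self.response_window_h <= 0:
            raise ConfigurationError("response window must be positive")
        if self.kind in ("ghrelin", "vehicle") and self.injection_time is None:
            raise ConfigurationError(f"{self.kind} protocol requires an injection_time")

    @staticmethod
    def spontaneous() -> "ProtocolSpec":
        return ProtocolSpec("spontaneous")

    @staticmethod
    def dark_onset(hours: float = 4.0) -> "ProtocolSpec":
        return ProtocolSpec("dark_onset", response_window_h=hours)

    @staticmethod
    def starve_refeed(schedule: LightSchedule = LightSchedule()) -> "ProtocolSpec":
        # food is withheld over exactly the dark cycle and restored at light on
        return ProtocolSpec(
            "starve_refeed",
            food_removed=(schedule.light_off, schedule.light_on),
            response_window_h=4.0,
        )

    @staticmethod
    def ghrelin(injection_time: time = time(8, 0)) -> "ProtocolSpec":
        return ProtocolSpec("ghrelin", injection_time=injection_time, response_window_h=2.0)

    @staticmethod
    def vehicle(injection_time: time = time(8, 0)) -> "ProtocolSpec":
        return ProtocolSpec("vehicle", injection_time=injection_time, response_window_h=2.0)


@dataclass(frozen=True)
class MealTimingParams:
    """Per-cycle meal process parameters.

    ``meals_per_cycle`` is the expected meal count in the 12-h cycle;
    sizes are truncated normal (lower bound keeps every meal above the
    0.03-g nibble threshold), durations truncated normal in minutes.
    """

    meals_per_cycle: float
    size_mean_kcal: float
    size_sd_kcal: float
    duration_mean_min: float
    duration_sd_min: float
    size_min_g: float = 0.04
    duration_min_min: float = 0.25

    def __post_init__(self):
        for name in ("meals_per_cycle", "size_mean_kcal", "size_sd_kcal",
                     "duration_mean_min", "duration_sd_min"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ZeroBlockParams:
    """Sampler for multi-hour zero-intake blocks (cachectic state only).

    Each spontaneous observation day receives clock-hour-aligned blocks with
    no hopper interactions at all: ``light_hours_total`` h in the light and
    ``dark_hours_total`` h in the dark, partitioned into 2–4 blocks of
    ``min_len``..``max_len`` consecutive hours.  Blocks avoid the first dark
    dark hour (the lights-off feeding response is preserved even in
    cachexia, after which feeding falters) and the earliest light hours
    (dawn feeding peak).

    The defaults (6 light + 5 dark block hours) are set so that *measured*
    zero-intake hours — blocks plus the occasional stochastically meal-free
    hour outside them, expected ~1 h/day at the cachectic feeding rates —
    average ~12 h/day, split ~7 light / ~5 dark.
    """

    light_hours_total: int = 6
    dark_hours_total: int = 5
    min_len: int = 2
    max_len: int = 8
    light_window: Tuple[int, int] = (3, 12)   # hour offsets within the light cycle
    dark_window: Tuple[int, int] = (1, 12)    # hour offsets within the dark cycle

    def __post_init__(self):
        if not (0 < self.min_len <= self.max_len):
            raise ConfigurationError("invalid zero-block length range")
        for total, window in ((self.light_hours_total, self.light_window),
                              (self.dark_hours_total, self.dark_window)):
            if total > window[1] - window[0]:
                raise ConfigurationError("zero-block hours do not fit in placement window")


@dataclass(frozen=True)
class EvokedBoostParams:
    """Transient multiplicative boost to meal initiation after a cue.

    The hazard multiplier is applied to the meal-initiation rate and the
    size multiplier to mean meal size for ``duration_h`` hours after the
    cue (food return or injection)."""

    hazard_mult: float = 1.0
    size_mult: float = 1.0
    duration_h: float = 2.0
    tail_hazard_mult: float = 1.0   # milder elevation for the rest of the window
    tail_duration_h: float = 0.0

    def __post_init__(self):
        if min(self.hazard_mult, self.size_mult, self.tail_hazard_mult) < 0:
            raise ConfigurationError("boost multipliers must be non-negative")


@dataclass(frozen=True)
class FeedingProcessParams:
    """Stochastic feeding process for one physiological state."""

    light: MealTimingParams
    dark: MealTimingParams
    #: per-hour meal-initiation hazard multipliers within each cycle
    #: (normalized internally to preserve the expected per-cycle count)
    hazard_shape_light: Tuple[float, ...] = (1.0,) * 12
    hazard_shape_dark: Tuple[float, ...] = (1.0,) * 12
    #: probability a meal is recorded as two hopper interactions separated by
    #: a short within-meal pause (always < 5 min, so segmentation re-merges)
    split_probability: float = 0.25
    pause_min_min: float = 0.2
    pause_max_min: float = 1.0
    #: between-animal trait variation (lognormal CVs, persistent across
    #: phases of a paired study): individual meal-size scale (mean-one) and
    #: meal-initiation interval scale (median-one); magnitudes follow the
    #: between-animal dispersion implied by published cohort SEMs
    between_animal_size_cv: float = TRAIT_SIZE_CV
    between_animal_gap_cv: float = TRAIT_GAP_CV
    #: sub-threshold hopper interactions (<= 0.03 g), events per hour
    nibble_rate_per_h: float = 1.5
    nibble_grams: Tuple[float, ...] = (0.01, 0.02, 0.03)
    nibble_weights: Tuple[float, ...] = (0.5, 0.3, 0.2)
    zero_blocks: Optional[ZeroBlockParams] = None
    refeed_boost: EvokedBoostParams = field(default_factory=EvokedBoostParams)
    ghrelin_boost: EvokedBoostParams = field(default_factory=EvokedBoostParams)

    def __post_init__(self):
        if not (0 <= self.split_probability <= 1):
            raise ConfigurationError("split_probability must lie in [0, 1]")
        if self.pause_max_min >= 5.0:
            raise ConfigurationError("within-meal pauses must stay below 5 min")
        if max(self.nibble_grams) > 0.03:
            raise ConfigurationError("nibble intakes must not exceed 0.03 g")
        if self.nibble_rate_per_h < 0:
            raise ConfigurationError("nibble rate must be non-negative")
        if len(self.hazard_shape_light) != 12 or len(self.hazard_shape_dark) != 12:
            raise ConfigurationError("hazard shapes must have 12 hourly entries")
        if min(self.hazard_shape_light + self.hazard_shape_dark) <= 0:
            raise ConfigurationError("hazard shape multipliers must be positive")


@dataclass(frozen=True)
class MetabolicParams:
    """Gas-exchange and activity trace parameters for one state.

    VO2 in L O2/h at the animal level (whole-animal, not mass-specific);
    RER setpoints are dimensionless cycle means; ambulatory/stationary
    rates are bout initiations per hour.
    """

    vo2_light_l_h: float = 0.085
    vo2_dark_l_h: float = 0.105
    vo2_noise_sd: float = 0.005
    rer_light: float = 0.85
    rer_dark: float = 0.95
    rer_noise_sd: float = 0.015
    #: transient RER elevation (carbohydrate oxidation) in the first hours
    #: after dark onset, tracking the nocturnal feeding burst
    rer_feeding_excursion: float = 0.02
    scan_interval_min: float = 10.0
    ambulatory_rate_light_per_h: float = 10.0
    ambulatory_rate_dark_per_h: float = 38.0
    stationary_rate_per_h: float = 20.0
    rearing_rate_per_h: float = 10.0
    n_beams: int = 16

    def __post_init__(self):
        if self.scan_interval_min <= 0:
            raise ConfigurationError("scan interval must be positive")
        if min(self.vo2_light_l_h, self.vo2_dark_l_h) <= 0:
            raise ConfigurationError("VO2 levels must be positive")
        for name in ("rer_light", "rer_dark"):
            if not (0.7 <= getattr(self, name) <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0.7, 1.0]")
        for name in ("ambulatory_rate_light_per_h", "ambulatory_rate_dark_per_h",
                     "stationary_rate_per_h", "rearing_rate_per_h"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic CLAMS cohort generator."""

    seed: int
    n_animals: int = 7
    state: str = "baseline"
    schedule: LightSchedule = field(default_factory=LightSchedule)
    diet_energy_density: float = 3.0
    feeding: FeedingProcessParams = None  # type: ignore[assignment]
    metabolic: MetabolicParams = None  # type: ignore[assignment]
    #: balance quantum: intakes are multiples of this many grams
    scale_resolution: float = 0.01

    def __post_init__(self):
        if self.state not in STATES:
            raise ConfigurationError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.n_animals < 1:
            raise ConfigurationError("n_animals must be >= 1")
        if self.diet_energy_density <= 0:
            raise ConfigurationError("diet energy density must be positive")
        if self.scale_resolution <= 0:
            raise ConfigurationError("scale resolution must be positive")
        from . import calibration  # deferred: calibration imports this module

        if self.feeding is None:
            object.__setattr__(self, "feeding", calibration.default_feeding_params(self.state))
        if self.metabolic is None:
            object.__setattr__(self, "metabolic", calibration.default_metabolic_params(self.state))

    @property
    def diet(self) -> DietSpec:
        return DietSpec(self.diet_energy_density)

    def animal_ids(self) -> list[str]:
        # ids are state-independent so the same virtual animal can be
        # observed in both phases of a paired study
        return [f"M{i + 1:02d}" for i in range(self.n_animals)]

    def with_state(self, state: str) -> "GeneratorConfig":
        """Same cohort and seed in the other physiological state."""
        from . import calibration

        return replace(
            self,
            state=state,
            feeding=calibration.default_feeding_params(state),
            metabolic=calibration.default_metabolic_params(state),
        )
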