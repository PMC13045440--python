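"""Evoked feeding responses: windowed intake after homeostatic cues.

Three paradigms are analysed, each as intake accumulated in a fixed window
anchored to the cue, within animal and phase:

``dark_onset``      the first hours (default 4) after lights-off — the
                    nocturnal feeding drive; the first dark hour is also
                    reported separately.
``starve_refeed``   refeeding after a 12-h dark-cycle fast, from the
                    moment food is returned at light onset; both a 1-h and
                    a 4-h window are first-class outputs.
``ghrelin``         intake for 2 h after an orexigenic ghrelin (or vehicle)
                    injection in the light cycle.

Events straddling a window edge contribute pro-rata by time.  Cumulative
trajectories are non-decreasing and end at the window total.  Phase
contrasts are percent change of cohort means with a paired t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import time
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import LightSchedule
from .errors import ContractError, ValidationError
from .stats import paired_t
from .energetics import percent_change

__all__ = [
    "EvokedResult",
    "EvokedContrast",
    "window_intake",
    "dark_onset_response",
    "refeed_response",
    "ghrelin_response",
    "evoked_contrast",
]


@dataclass
class EvokedResult:
    """Windowed-intake analysis for one paradigm."""

    paradigm: str
    window_h: float
    #: one row per animal(-phase): mean window intake in g over analysed days
    per_animal: pd.DataFrame
    #: hourly cumulative intake: animal(-phase) x hour (1..window) in g
    trajectory: pd.DataFrame
    windows: Tuple[float, ...] = ()


@dataclass
class EvokedContrast:
    paradigm: str
    means: Dict[str, float]          # phase -> cohort mean intake (g)
    percent_change: float            # rounded to the nearest whole percent
    pvalue: float
    n_pairs: int


def _prorata(starts, ends, intakes, w0, w1) -> float:
    """Intake inside [w0, w1): events split pro-rata by time overlap."""
    total = 0.0
    for s, e, w in zip(starts, ends, intakes):
        if e <= s:  # instantaneous event: in or out by its start
            if w0 <= s < w1:
                total += w
            continue
        overlap = min(e, w1) - max(s, w0)
        if overlap > 0:
            total += w * (overlap / (e - s))
    return total


def window_intake(events: pd.DataFrame, window_start, window_end) -> pd.DataFrame:
    """Per animal(-phase) pro-rata intake (g) inside a single time window."""
    cols = ["animal_id"] + (["phase"] if "phase" in events.columns else [])
    w0, w1 = pd.Timestamp(window_start), pd.Timestamp(window_end)
    rows = []
    for key, grp in events.groupby(cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            key
            + (
                _prorata(
                    grp["start"].to_numpy(),
                    grp["end"].to_numpy(),
                    grp["intake_g"].to_numpy(),
                    np.datetime64(w0),
                    np.datetime64(w1),
                ),
            )
        )
    return pd.DataFrame(rows, columns=cols + ["intake_g"])


def _windowed_by_day(
    events: pd.DataFrame,
    schedule: LightSchedule,
    offset_h: float,
    hours: float,
    days: Optional[Sequence[int]],
    paradigm: str,
    require_coverage: bool = True,
) -> EvokedResult:
    """Window analysis anchored at light-onset + offset of each analysed day."""
    if events.empty:
        raise ContractError(f"{paradigm}: empty event record")
    cols = ["animal_id"] + (["phase"] if "phase" in events.columns else [])
    n_hours = int(np.ceil(hours))

    per_rows: List[tuple] = []
    traj_rows: List[tuple] = []
    for key, grp in events.groupby(cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        grp_days = days if days is not None else sorted({schedule.day_index(t) for t in grp["start"]})
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        intakes = grp["intake_g"].to_numpy()
        record_lo = starts.min()
        day_totals: List[float] = []
        day_cums: List[np.ndarray] = []
        for day in grp_days:
            w0 = np.datetime64(schedule.day_anchor(day) + pd.Timedelta(hours=offset_h))
            w1 = w0 + np.timedelta64(int(hours * 3600), "s")
            if require_coverage and record_lo > w1:
                raise ContractError(
                    f"{paradigm}: record of {key!r} does not cover the day-{day} window"
                )
            cum = np.array(
                [
                    _prorata(starts, ends, intakes, w0,
                             w0 + np.timedelta64(int(min(h, hours) * 3600), "s"))
                    for h in range(1, n_hours + 1)
                ]
            )
            day_totals.append(_prorata(starts, ends, intakes, w0, w1))
            day_cums.append(cum)
        if not day_totals:
            continue
        mean_cum = np.mean(day_cums, axis=0)
        first_hour = float(mean_cum[0])
        per_rows.append(key + (float(np.mean(day_totals)), first_hour))
        for h, v in enumerate(mean_cum, start=1):
            traj_rows.append(key + (h, float(v)))

    per_animal = pd.DataFrame(per_rows, columns=cols + ["intake_g", "first_hour_g"])
    trajectory = pd.DataFrame(traj_rows, columns=cols + ["hour", "cumulative_g"])
    return EvokedResult(paradigm=paradigm, window_h=hours,
                        per_animal=per_animal, trajectory=trajectory)


def dark_onset_response(
    events: pd.DataFrame,
    schedule: LightSchedule,
    hours: float = 4.0,
    days: Optional[Sequence[int]] = None,
) -> EvokedResult:
    """Cumulative intake over the first ``hours`` of the dark cycle.

    Averaged over the analysed days per animal(-phase); the first dark
    hour is reported separately in ``per_animal['first_hour_g']``.
    """
    return _windowed_by_day(
        events, schedule, offset_h=schedule.light_hours, hours=hours,
        days=days, paradigm="dark_onset",
    )


def refeed_response(
    events: pd.DataFrame,
    schedule: LightSchedule,
    refeed_day: int,
    windows: Tuple[float, float] = (1.0, 4.0),
) -> EvokedResult:
    """Refeeding intake from light onset of ``refeed_day`` after a dark-cycle fast.

    Validates that the preceding dark cycle (the starvation window) is
    truly free of feeding events; any event there is a protocol violation.
    Both requested windows (default 1 h and 4 h) are reported:
    ``intake_g`` holds the longest window, ``intake_{w}h_g`` each window.
    """
    anchor = schedule.day_anchor(refeed_day)
    starve0 = np.datetime64(anchor - pd.Timedelta(hours=schedule.dark_hours))
    starve1 = np.datetime64(anchor)
    if not events.empty:
        s = events["start"].to_numpy()
        e = events["end"].to_numpy()
        inside = (e > starve0) & (s < starve1)
        if inside.any():
            first = events.loc[inside].iloc[0]
            raise ValidationError(
                f"feeding event for {first['animal_id']!r} at {first['start']} "
                "falls inside the starvation window"
            )
    hours = max(windows)
    result = _windowed_by_day(
        events, schedule, offset_h=0.0, hours=hours, days=[refeed_day],
        paradigm="starve_refeed",
    )
    # attach every requested window as its own column
    traj = result.trajectory
    for w in windows:
        col = f"intake_{w:g}h_g"
        sub = traj.loc[traj["hour"] == int(np.ceil(w)), :]
        keys = [c for c in ("animal_id", "phase") if c in result.per_animal.columns]
        result.per_animal = result.per_animal.merge(
            sub.rename(columns={"cumulative_g": col})[keys + [col]], on=keys, how="left"
        )
    result.windows = tuple(windows)
    return result


def ghrelin_response(
    events: pd.DataFrame,
    schedule: LightSchedule,
    injection_time: Optional[time],
    day: int,
    window_h: float = 2.0,
    paradigm: str = "ghrelin",
) -> EvokedResult:
    """Intake over [injection, injection + window] on the protocol day.

    The vehicle arm is summarized identically (``paradigm='vehicle'``)."""
    if injection_time is None:
        raise ContractError("ghrelin/vehicle analysis requires an injection time")
    anchor = schedule.day_anchor(day)
    inj_min = injection_time.hour * 60 + injection_time.minute
    on_min = schedule.light_on.hour * 60 + schedule.light_on.minute
    offset_h = ((inj_min - on_min) % (24 * 60)) / 60.0
    return _windowed_by_day(
        events, schedule, offset_h=offset_h, hours=window_h, days=[day],
        paradigm=paradigm,
    )


def evoked_contrast(
    per_animal: pd.DataFrame,
    paradigm: str,
    value_col: str = "intake_g",
    phases: Tuple[str, str] = ("baseline", "kpc_d14"),
) -> EvokedContrast:
    """Within-animal phase contrast: percent change of cohort means + paired t.

    Animals missing either phase are dropped with a warning."""
    if "phase" not in per_animal.columns:
        raise ContractError("evoked_contrast requires a 'phase' column")
    wide = per_animal.pivot_table(index="animal_id", columns="phase",
                                  values=value_col, aggfunc="mean")
    for ph in phases:
        if ph not in wide.columns:
            raise ContractError(f"phase {ph!r} absent from evoked results")
    complete = wide.dropna(subset=list(phases))
    if len(complete) < len(wide):
        warnings.warn(
            f"{len(wide) - len(complete)} animal(s) lack both phases; dropped",
            stacklevel=2,
        )
    a, b = complete[phases[0]].to_numpy(), complete[phases[1]].to_numpy()
    test = paired_t(a, b)
    means = {phases[0]: float(a.mean()), phases[1]: float(b.mean())}
    return EvokedContrast(
        paradigm=paradigm,
        means=means,
        percent_change=percent_change(means[phases[0]], means[phases[1]], rounded=True),
        pvalue=test.pvalue,
        n_pairs=test.n,
    )
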