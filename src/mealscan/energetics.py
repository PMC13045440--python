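"""Indirect-calorimetry and locomotor-activity analytics.

Gas exchange: the respiratory exchange ratio RER = VCO2/VO2 indexes fuel
selection (~0.7 pure fat oxidation, ~1.0 pure carbohydrate).  Heat
production (energy expenditure, kcal/h) follows the Oxymax convention
``heat = CV(RER) * VO2`` where the caloric value CV (kcal per litre O2) is
the linear interpolation of Lusk's oxycalorific table,

    CV = 3.815 + 1.232 * RER          (kcal / L O2)

so CV(0.707) = 4.686 and CV(1.0) = 5.047 kcal/L, the published endpoints.
RER outside [0.7, 1.0] (protein oxidation, lipogenesis, sensor noise) is
clamped into the table's domain with a warning.

Activity: ambulation is counted from horizontal (X-axis) infrared beam
breaks.  A maximal run of breaks separated by less than a quiescence gap
is one locomotor episode; it counts as *ambulatory* only if at least two
distinct, spatially adjacent beams are broken in succession — repeated
breaks of a single beam (grooming, scratching) are stationary and ignored.
"""

from __future__ import annotations

import warnings
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import LightSchedule
from .errors import ContractError

LUSK_INTERCEPT = 3.815
LUSK_SLOPE = 1.232
RER_TABLE_RANGE = (0.7, 1.0)

DEFAULT_QUIESCENCE_GAP_S = 1.0


def rer(vo2, vco2):
    """Respiratory exchange ratio VCO2/VO2 (element-wise)."""
    vo2 = np.asarray(vo2, float)
    vco2 = np.asarray(vco2, float)
    if np.any(vo2 <= 0):
        raise ContractError("RER requires VO2 > 0")
    out = vco2 / vo2
    return float(out) if out.ndim == 0 else out


def lusk_caloric_value(rer_value):
    """Caloric value of O2 (kcal/L) from the linear Lusk interpolation.

    Values outside the table domain [0.7, 1.0] are clamped with a warning.
    """
    arr = np.asarray(rer_value, float)
    lo, hi = RER_TABLE_RANGE
    if np.any((arr < lo) | (arr > hi)):
        warnings.warn(
            "RER outside the oxycalorific table domain [0.7, 1.0]; clamping",
            stacklevel=2,
        )
        arr = np.clip(arr, lo, hi)
    out = LUSK_INTERCEPT + LUSK_SLOPE * arr
    return float(out) if out.ndim == 0 else out


def heat(vo2, vco2):
    """Heat production (kcal/h) = CV(RER) x VO2 (L/h)."""
    vo2 = np.asarray(vo2, float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv = lusk_caloric_value(rer(vo2, vco2))
    out = cv * vo2
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# ambulatory counting


def _runs(times_s: np.ndarray, gap_s: float) -> List[slice]:
    """Maximal runs of consecutive breaks separated by < gap_s seconds."""
    if len(times_s) == 0:
        return []
    splits = np.flatnonzero(np.diff(times_s) >= gap_s) + 1
    bounds = np.concatenate([[0], splits, [len(times_s)]])
    return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def _is_ambulatory(beams: np.ndarray) -> bool:
    """A run is ambulatory iff two distinct adjacent beams break in succession."""
    if len(beams) < 2:
        return False
    return bool(np.any(np.abs(np.diff(beams)) == 1))


def ambulatory_count(
    stream: pd.DataFrame,
    schedule: Optional[LightSchedule] = None,
    gap_s: float = DEFAULT_QUIESCENCE_GAP_S,
) -> pd.DataFrame:
    """Count ambulatory episodes per animal (and phase/cycle/day when known).

    Only X-axis (horizontal) breaks are considered.  The stream must be
    time-ordered per animal.  Episodes are assigned to the cycle and day of
    their first break when a schedule is given.
    """
    cols = ["animal_id"] + (["phase"] if "phase" in stream.columns else [])
    out_cols = cols + (["day", "cycle"] if schedule is not None else []) + ["ambulatory_count"]
    if stream.empty:
        return pd.DataFrame(columns=out_cols)

    rows = []
    horizontal = stream.loc[stream["axis"] == "X"]
    for key, grp in horizontal.groupby(cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        t = grp["time"].to_numpy()
        if np.any(np.diff(t) < np.timedelta64(0, "s")):
            raise ContractError(f"activity stream of {key!r} is not time-ordered")
        secs = (t - t[0]) / np.timedelta64(1, "s") if len(t) else np.array([])
        beams = grp["beam_index"].to_numpy()
        starts = grp["time"].to_numpy()
        counts: dict = {}
        for run in _runs(secs, gap_s):
            if not _is_ambulatory(beams[run]):
                continue
            if schedule is None:
                counts[()] = counts.get((), 0) + 1
            else:
                first = pd.Timestamp(starts[run.start])
                sub = (schedule.day_index(first), schedule.cycle_at(first))
                counts[sub] = counts.get(sub, 0) + 1
        if schedule is None:
            rows.append(key + (counts.get((), 0),))
        else:
            for sub, c in sorted(counts.items()):
                rows.append(key + sub + (c,))
    return pd.DataFrame(rows, columns=out_cols)


# ---------------------------------------------------------------------------
# summaries


def cycle_energy_summary(
    samples: pd.DataFrame,
    activity: Optional[pd.DataFrame],
    schedule: LightSchedule,
) -> pd.DataFrame:
    """Per animal(-phase) x cycle means of VO2, RER and heat, plus ambulation.

    Ambulatory counts are totals per cycle divided by the number of
    observed days (episodes per 12-h cycle per day).
    """
    cols = ["animal_id"] + (["phase"] if "phase" in samples.columns else [])
    df = samples.copy()
    if df.empty:
        return pd.DataFrame(
            columns=cols + ["cycle", "vo2_l_h", "rer", "heat_kcal_h", "ambulatory_per_day"]
        )
    df["cycle"] = [schedule.cycle_at(ts) for ts in df["time"]]
    df["rer_sample"] = rer(df["vo2_l_h"], df["vco2_l_h"])
    df["heat_sample"] = heat(df["vo2_l_h"], df["vco2_l_h"])
    agg = (
        df.groupby(cols + ["cycle"], sort=True)
        .agg(
            vo2_l_h=("vo2_l_h", "mean"),
            rer=("rer_sample", "mean"),
            heat_kcal_h=("heat_sample", "mean"),
        )
        .reset_index()
    )
    if activity is not None and not activity.empty:
        counts = ambulatory_count(activity, schedule=schedule)
        if not counts.empty:
            per_day = (
                counts.groupby(cols + ["cycle"], sort=True)
                .agg(total=("ambulatory_count", "sum"), n_days=("day", "nunique"))
                .reset_index()
            )
            per_day["ambulatory_per_day"] = per_day["total"] / per_day["n_days"]
            agg = agg.merge(
                per_day[cols + ["cycle", "ambulatory_per_day"]],
                on=cols + ["cycle"],
                how="left",
            )
    if "ambulatory_per_day" not in agg.columns:
        agg["ambulatory_per_day"] = np.nan
    return agg


def percent_change(a: float, b: float, rounded: bool = False) -> float:
    """Percent change from a to b: 100 * (b - a) / a.

    ``rounded`` rounds to the nearest whole percent (the convention used
    when quoting headline contrasts).  a = 0 is undefined and flagged.
    """
    if a == 0:
        warnings.warn("percent change from a zero reference is undefined", stacklevel=2)
        return float("nan")
    value = 100.0 * (b - a) / a
    return float(round(value)) if rounded else value


def absolute_change(a: float, b: float) -> float:
    """Plain difference b - a (e.g. a meal-duration shift in minutes)."""
    return b - a
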