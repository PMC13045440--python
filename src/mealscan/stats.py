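"""Cohort-level summaries and statistical comparisons over meal series.

Covers hourly intake binning and zero-intake hours, per-cycle summaries
(totals, meal counts, microstructure means), linear mixed-effects phase
contrasts with animal random intercepts, paired t-tests, one-tailed
Fisher's exact tests of proportions, 2-point profile smoothing, satiety-
ratio time-of-day profiles, and tidy raster/radial export tables.

Conventions
-----------
* Hourly bins are aligned to clock hours, bin 0 starting at light onset;
  events straddling a bin boundary are split pro-rata by time.
* An hour is a zero-intake hour iff its binned intake is exactly 0 g.
* Per-cycle interval statistics (IMI, SR) group each interval with the
  cycle of its *preceding* meal.
* Undefined means (an animal-cycle with no meals or no intervals)
  propagate as missing values and reduce n — never as zeros.
* p-values are reported raw; no multiple-testing adjustment is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .config import DietSpec, LightSchedule
from .errors import ContractError, DegenerateDataError

__all__ = [
    "hourly_bin",
    "zero_intake_hours",
    "cycle_summary",
    "LmmResult",
    "fit_lmm",
    "PairedTResult",
    "paired_t",
    "ProportionTestResult",
    "fisher_one_tailed",
    "smooth_profile",
    "sr_time_profile",
    "raster_export",
    "radial_export",
    "percent_share",
    "fold_change",
]

MICROSTRUCTURE_COLUMNS = {
    "size_kcal": "meal_size_kcal",
    "duration_min": "meal_duration_min",
    "imi_next": "imi_min",
    "sr_next": "sr_min_per_01kcal",
    "ingestion_rate": "ingestion_rate_kcal_min",
}


def _group_cols(df: pd.DataFrame) -> List[str]:
    return ["animal_id"] + (["phase"] if "phase" in df.columns else [])


# ---------------------------------------------------------------------------
# hourly binning


def hourly_bin(
    events: pd.DataFrame,
    schedule: LightSchedule,
    diet: Optional[DietSpec] = None,
    days: Optional[Sequence[int]] = None,
    prorate: bool = True,
) -> pd.DataFrame:
    """24 x 1 h binned intake per animal-day (complete zero-filled grid).

    Intake of an event is attributed pro-rata by time to the clock-hour
    bins it overlaps (``prorate=False`` attributes everything to the bin
    containing the start).  Bin 0 starts at light onset.  ``days`` fixes
    the day range of the grid; by default it spans the observed days of
    each animal(-phase) record.
    """
    cols = _group_cols(events) if len(events) else ["animal_id"]
    records: Dict[tuple, Dict[int, float]] = {}
    groups: Dict[tuple, tuple] = {}

    if not events.empty:
        anchor = schedule.day_anchor(0)
        starts = (events["start"] - anchor) / pd.Timedelta(seconds=1)
        ends = (events["end"] - anchor) / pd.Timedelta(seconds=1)
        keys = list(zip(*(events[c] for c in cols)))
        for key, s, e, w in zip(keys, starts.to_numpy(), ends.to_numpy(),
                                events["intake_g"].to_numpy()):
            bins = records.setdefault(key, {})
            groups[key] = key
            if e <= s or not prorate:
                k = int(np.floor(s / 3600.0))
                bins[k] = bins.get(k, 0.0) + w
                continue
            k0, k1 = int(np.floor(s / 3600.0)), int(np.ceil(e / 3600.0))
            span = e - s
            for k in range(k0, k1):
                overlap = min(e, (k + 1) * 3600.0) - max(s, k * 3600.0)
                if overlap > 0:
                    bins[k] = bins.get(k, 0.0) + w * overlap / span

    rows = []
    light_on_hour = schedule.light_on.hour
    for key, bins in sorted(records.items(), key=lambda kv: kv[0]):
        if days is None:
            day_lo = min(bins) // 24 if bins else 0
            day_hi = max(bins) // 24 if bins else 0
            day_range: Iterable[int] = range(day_lo, day_hi + 1)
        else:
            day_range = days
        for day in day_range:
            for b in range(24):
                k = day * 24 + b
                rows.append(key + (day, b, (light_on_hour + b) % 24, bins.get(k, 0.0)))
    out = pd.DataFrame(rows, columns=cols + ["day", "bin", "clock_hour", "intake_g"])
    if diet is not None:
        out["intake_kcal"] = out["intake_g"] * diet.energy_density
    return out


def zero_intake_hours(matrix: pd.DataFrame, schedule: LightSchedule) -> pd.DataFrame:
    """Per animal(-phase)-day counts of hours with exactly zero intake."""
    cols = [c for c in ("animal_id", "phase") if c in matrix.columns]
    if matrix.empty:
        return pd.DataFrame(columns=cols + ["day", "zero_total", "zero_light", "zero_dark"])
    light_bins = int(round(schedule.light_hours))
    df = matrix.assign(
        _zero=(matrix["intake_g"] == 0.0),
        _light=matrix["bin"] < light_bins,
    )
    agg = (
        df.groupby(cols + ["day"], sort=True)
        .apply(
            lambda g: pd.Series(
                {
                    "zero_total": int(g["_zero"].sum()),
                    "zero_light": int((g["_zero"] & g["_light"]).sum()),
                    "zero_dark": int((g["_zero"] & ~g["_light"]).sum()),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return agg


# ---------------------------------------------------------------------------
# per-cycle summary


def cycle_summary(
    meals: pd.DataFrame,
    schedule: LightSchedule,
    n_days: Optional[int] = None,
) -> pd.DataFrame:
    """Per animal(-phase) x cycle totals and microstructure means.

    Totals and meal counts are expressed per day; ``n_days`` defaults to
    the span of observed days in each record.  Mean IMI/SR use the
    intervals whose preceding meal lies in the cycle; records with no such
    intervals yield missing values.
    """
    cols = _group_cols(meals) if len(meals) else ["animal_id"]
    out_cols = cols + ["cycle", "n_days", "n_meals", "meals_per_day",
                       "intake_kcal_per_day", "intake_g_per_day",
                       *MICROSTRUCTURE_COLUMNS.values()]
    if meals.empty:
        return pd.DataFrame(columns=out_cols)

    rows = []
    for key, grp in meals.groupby(cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        span = n_days if n_days is not None else int(grp["day"].max() - grp["day"].min() + 1)
        for cycle in ("light", "dark"):
            sub = grp.loc[grp["cycle"] == cycle]
            if sub.empty:
                continue
            row = dict(zip(cols, key))
            row.update(
                cycle=cycle,
                n_days=span,
                n_meals=len(sub),
                meals_per_day=len(sub) / span,
                intake_kcal_per_day=sub["size_kcal"].sum() / span,
                intake_g_per_day=sub["intake_g"].sum() / span,
            )
            for src, dst in MICROSTRUCTURE_COLUMNS.items():
                vals = sub[src].dropna()
                row[dst] = vals.mean() if len(vals) else np.nan
            rows.append(row)
    return pd.DataFrame(rows, columns=out_cols)


# ---------------------------------------------------------------------------
# linear mixed model


@dataclass
class LmmResult:
    """Phase contrast for one meal-level parameter from a mixed model."""

    parameter: str
    phases: Tuple[str, str]
    emm: Dict[str, Tuple[float, float]]  # phase -> (estimated marginal mean, SEM)
    contrast: float                      # phases[1] - phases[0]
    se: float
    pvalue: float
    n_animals: int
    n_obs: int
    fallback: bool = False               # True when refit as pooled OLS

    def emm_of(self, phase: str) -> float:
        return self.emm[phase][0]


def fit_lmm(
    data: pd.DataFrame,
    value_col: str = "value",
    phase_col: str = "phase",
    animal_col: str = "animal_id",
    parameter: Optional[str] = None,
) -> LmmResult:
    """REML linear mixed model: value ~ phase with a per-animal random intercept.

    Estimated marginal means are the model-based phase means; their SEMs
    come from the fixed-effect covariance.  A singular or non-converging
    random-effect structure triggers a pooled fixed-effects (OLS) refit
    with a warning.  Requires exactly two phases, both observed in >= 2
    animals overall.
    """
    df = data[[animal_col, phase_col, value_col]].dropna()
    phases = sorted(df[phase_col].unique(), key=lambda p: (p != "baseline", p))
    if len(phases) != 2:
        raise ContractError(f"fit_lmm requires exactly 2 phases, got {list(phases)}")
    if df[animal_col].nunique() < 2:
        raise ContractError("fit_lmm requires >= 2 animals")

    ref, alt = phases
    y = df[value_col].to_numpy(float)
    x = np.column_stack([np.ones(len(df)), (df[phase_col] == alt).to_numpy(float)])
    groups = df[animal_col].to_numpy()

    beta = cov = None
    fallback = False
    if np.var(y) > 0:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                model = sm.MixedLM(y, x, groups=groups)
                fit = model.fit(reml=True)
                bse_ok = np.all(np.isfinite(fit.bse_fe))
                re_var = float(np.asarray(fit.cov_re)[0, 0])
                if bse_ok and re_var > 1e-10:
                    beta = np.asarray(fit.fe_params)
                    cov = np.asarray(fit.cov_params())[:2, :2]
        except (np.linalg.LinAlgError, ValueError):
            beta = None
    if beta is None:
        fallback = True
        warnings.warn(
            "singular or degenerate random-effect structure; "
            "falling back to a pooled fixed-effects fit",
            stacklevel=2,
        )
        ols = sm.OLS(y, x).fit()
        beta, cov = np.asarray(ols.params), np.asarray(ols.cov_params())

    emm = {
        ref: (float(beta[0]), float(np.sqrt(max(cov[0, 0], 0.0)))),
        alt: (
            float(beta[0] + beta[1]),
            float(np.sqrt(max(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1], 0.0))),
        ),
    }
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    if se > 0:
        pvalue = float(2 * scipy.stats.norm.sf(abs(beta[1]) / se))
    else:
        pvalue = np.nan if beta[1] != 0 else 1.0
    return LmmResult(
        parameter=parameter or value_col,
        phases=(ref, alt),
        emm=emm,
        contrast=float(beta[1]),
        se=se,
        pvalue=pvalue,
        n_animals=int(df[animal_col].nunique()),
        n_obs=len(df),
        fallback=fallback,
    )


def lmm_by_cycle(
    meals: pd.DataFrame,
    value_col: str,
    schedule: Optional[LightSchedule] = None,
) -> Dict[str, LmmResult]:
    """Fit the phase mixed model separately within each light/dark cycle."""
    out = {}
    for cycle in ("light", "dark"):
        sub = meals.loc[meals["cycle"] == cycle]
        if sub[value_col].dropna().empty:
            continue
        out[cycle] = fit_lmm(sub, value_col=value_col, parameter=f"{value_col}[{cycle}]")
    return out


# ---------------------------------------------------------------------------
# classical tests


@dataclass
class PairedTResult:
    mean_difference: float
    t: float
    pvalue: float
    n: int


def paired_t(a: Sequence[float], b: Sequence[float]) -> PairedTResult:
    """Classical two-sided paired t-test on complete pairs.

    Identical samples give t=0, p=1; zero variance of the differences with
    a non-zero mean difference is degenerate and raises."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ContractError("paired_t requires equal-length samples")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ContractError("paired_t requires >= 2 complete pairs")
    d = b - a
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return PairedTResult(0.0, 0.0, 1.0, len(d))
        raise DegenerateDataError(
            "paired differences have zero variance but non-zero mean"
        )
    t, p = scipy.stats.ttest_rel(b, a)
    return PairedTResult(float(d.mean()), float(t), float(p), len(d))


@dataclass
class ProportionTestResult:
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    pvalue: float
    direction: str  # 'greater' or 'less' (odds ratio of row 1 vs row 2)


def fisher_one_tailed(table, direction: str = "greater") -> ProportionTestResult:
    """One-tailed Fisher's exact test on a 2x2 count table.

    ``direction='greater'`` tests whether row 1 is enriched in column 1
    relative to row 2 (odds ratio > 1); ``'less'`` the opposite tail.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ContractError("fisher_one_tailed requires a 2x2 table")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)) or np.any(arr < 0):
            raise ContractError("counts must be non-negative integers")
        arr = arr.astype(int)
    if arr.sum() == 0:
        # both margins zero: the hypergeometric law is undefined
        raise ContractError("all-zero table")
    if direction not in ("greater", "less"):
        raise ContractError(f"unknown direction {direction!r}")
    _, p = scipy.stats.fisher_exact(arr, alternative=direction)
    return ProportionTestResult(tuple(map(tuple, arr.tolist())), float(p), direction)


# ---------------------------------------------------------------------------
# profiles & exports


def smooth_profile(values: np.ndarray | pd.DataFrame, window: int = 2):
    """2-point moving average with a +/- SEM envelope across animals.

    ``values`` is animals x timepoints (a 1-D series is treated as one
    animal, envelope omitted).  Series shorter than ``window`` are returned
    unchanged with a warning.  Output length is T - window + 1.
    """
    arr = np.atleast_2d(np.asarray(values, float))
    n_animals, t = arr.shape
    if t < window:
        warnings.warn("series shorter than the smoothing window; returned unchanged",
                      stacklevel=2)
        mean = arr.mean(axis=0)
        sem = scipy.stats.sem(arr, axis=0) if n_animals > 1 else np.full(t, np.nan)
        return mean, sem
    kernel = np.ones(window) / window
    smoothed = np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="valid"), 1, arr
    )
    mean = smoothed.mean(axis=0)
    sem = (
        scipy.stats.sem(smoothed, axis=0)
        if n_animals > 1
        else np.full(smoothed.shape[1], np.nan)
    )
    return mean, sem


def sr_time_profile(meals: pd.DataFrame, bin_hours: int = 2) -> pd.DataFrame:
    """Satiety-ratio means per clock bin of the preceding meal's start.

    Bins are ``bin_hours`` wide and anchored at midnight clock time; empty
    bins are simply absent from the output."""
    cols = [c for c in ("phase",) if c in meals.columns]
    if meals.empty:
        return pd.DataFrame(columns=cols + ["clock_bin_start", "sr_mean", "sr_sem", "n"])
    df = meals.dropna(subset=["sr_next"]).copy()
    df["clock_bin_start"] = (df["start"].dt.hour // bin_hours) * bin_hours
    agg = (
        df.groupby(cols + ["clock_bin_start"], sort=True)["sr_next"]
        .agg(sr_mean="mean", sr_sem=lambda v: scipy.stats.sem(v) if len(v) > 1 else np.nan,
             n="size")
        .reset_index()
    )
    return agg


def raster_export(meals: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready meal raster: one row per meal with clock onset and duration."""
    cols = _group_cols(meals) if len(meals) else ["animal_id"]
    out_cols = cols + ["day", "onset_clock_h", "duration_min", "cycle"]
    if meals.empty:
        return pd.DataFrame(columns=out_cols)
    df = meals.sort_values(cols + ["start"], kind="mergesort")
    out = df[cols + ["day", "duration_min", "cycle"]].copy()
    out.insert(len(cols) + 1, "onset_clock_h",
               df["start"].dt.hour + df["start"].dt.minute / 60.0
               + df["start"].dt.second / 3600.0)
    return out.reset_index(drop=True)[out_cols]


def radial_export(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean intake per clock hour around the 24-h dial (per phase if present).

    Row sums over the 24 bins equal the mean daily intake."""
    cols = [c for c in ("phase",) if c in matrix.columns]
    value_cols = [c for c in ("intake_g", "intake_kcal") if c in matrix.columns]
    if matrix.empty:
        return pd.DataFrame(columns=cols + ["bin", "clock_hour"] + value_cols)
    agg = (
        matrix.groupby(cols + ["bin", "clock_hour"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )
    return agg


# ---------------------------------------------------------------------------
# worked-example helpers


def percent_share(part: float, whole: float) -> float:
    """Percentage share of a component in a total (e.g. light-cycle intake)."""
    if whole == 0:
        raise ContractError("whole must be non-zero")
    return 100.0 * part / whole


def fold_change(reference: float, value: float) -> float:
    """value / reference (e.g. satiety-ratio fold increase)."""
    if reference == 0:
        raise ContractError("reference must be non-zero")
    return value / reference
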