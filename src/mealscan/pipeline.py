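"""End-to-end orchestration: simulate -> segment -> summarize -> energy ->
evoked -> report, with a run manifest for reproducibility.

Each stage reads/writes the documented file formats in one output
directory, so stages can be re-run individually (the CLI exposes them) or
as a whole via :func:`run_pipeline`.  Given a fixed master seed the whole
bundle is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from . import __version__
from .config import DietSpec, GeneratorConfig, LightSchedule
from .errors import ConfigurationError
from .evoked import dark_onset_response, evoked_contrast, ghrelin_response, refeed_response
from .energetics import cycle_energy_summary
from .io import (
    StudyManifest,
    read_activity,
    read_calorimetry,
    read_events,
    read_manifest,
    write_activity,
    write_calorimetry,
    write_events,
    write_manifest,
)
from .segmentation import MEAL_MIN_IMI_MIN, MEAL_MIN_SIZE_G, segment
from .simulate import generate_study
from .stats import (
    cycle_summary,
    fisher_one_tailed,
    fit_lmm,
    hourly_bin,
    paired_t,
    radial_export,
    raster_export,
    zero_intake_hours,
)

log = logging.getLogger("mealscan")

MEAL_FILE_COLUMNS = [
    "animal_id", "phase", "start", "end", "intake_g", "n_events",
    "duration_min", "size_kcal", "cycle", "day",
    "imi_next", "sr_next", "ingestion_rate",
]

LMM_PARAMETERS = {
    "imi_next": "imi_min",
    "sr_next": "sr_min_per_01kcal",
    "size_kcal": "meal_size_kcal",
    "duration_min": "meal_duration_min",
    "ingestion_rate": "ingestion_rate_kcal_min",
}


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    seed: int
    out_dir: str
    n_animals: int = 7
    min_imi: float = MEAL_MIN_IMI_MIN
    min_size: float = MEAL_MIN_SIZE_G
    diet_energy_density: float = 3.0

    def __post_init__(self):
        if self.min_imi <= 0 or self.min_size < 0:
            raise ConfigurationError("segmentation thresholds must be positive")

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            seed=self.seed,
            n_animals=self.n_animals,
            diet_energy_density=self.diet_energy_density,
        )


def _out(path: Path, name: str) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    return path / name


def _write_meals(meals: pd.DataFrame, path: Path) -> None:
    df = meals.copy()
    for col in ("start", "end"):
        df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    cols = [c for c in MEAL_FILE_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, lineterminator="\n")


def _read_meals(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal_id": str})
    for col in ("start", "end"):
        df[col] = pd.to_datetime(df[col], format="ISO8601")
    return df


def _attach_phase(df: pd.DataFrame, manifest: StudyManifest, schedule: LightSchedule,
                  time_col: str) -> pd.DataFrame:
    df = df.copy()
    df["phase"] = [manifest.phase_of_day(schedule.day_index(t)) for t in df[time_col]]
    return df


# ---------------------------------------------------------------------------
# stages


def simulate_stage(config: PipelineConfig) -> Dict[str, int]:
    out = Path(config.out_dir)
    study = generate_study(config.generator_config())
    write_events(study.events, _out(out, "events.csv"))
    write_calorimetry(study.calorimetry, _out(out, "calorimetry.csv"))
    write_activity(study.activity, _out(out, "activity.csv"))
    write_manifest(study.manifest, _out(out, "manifest.yaml"))
    counts = {
        "events": len(study.events),
        "calorimetry_samples": len(study.calorimetry),
        "beam_breaks": len(study.activity),
    }
    log.info("simulate: %s", counts)
    return counts


def segment_stage(config: PipelineConfig) -> Dict[str, int]:
    out = Path(config.out_dir)
    manifest = read_manifest(out / "manifest.yaml")
    events = read_events(out / "events.csv", manifest)
    events = _attach_phase(events, manifest, manifest.schedule, "start")
    meals = segment(
        events,
        DietSpec(manifest.diet_energy_density),
        manifest.schedule,
        min_imi=config.min_imi,
        min_size=config.min_size,
    )
    _write_meals(meals, _out(out, "meals.csv"))
    counts = {"events_in": len(events), "meals_out": len(meals)}
    log.info("segment: %s", counts)
    return counts


def summarize_stage(config: PipelineConfig) -> Dict[str, int]:
    out = Path(config.out_dir)
    manifest = read_manifest(out / "manifest.yaml")
    schedule = manifest.schedule
    diet = DietSpec(manifest.diet_energy_density)
    meals = _read_meals(out / "meals.csv")
    events = _attach_phase(read_events(out / "events.csv", manifest), manifest, schedule, "start")

    spont_days = {
        ph: manifest.days(phase=ph, kind="spontaneous") for ph in manifest.phases()
    }
    spont_all = sorted(set().union(*spont_days.values())) if spont_days else []
    ev_spont = events.loc[events["start"].map(lambda t: schedule.day_index(t)).isin(spont_all)]
    meals_spont = meals.loc[meals["day"].isin(spont_all)] if len(meals) else meals

    summary = cycle_summary(meals_spont, schedule)
    summary.to_csv(_out(out, "summary_cycle.csv"), index=False, lineterminator="\n")

    hourly = hourly_bin(ev_spont, schedule, diet=diet) if len(ev_spont) else hourly_bin(
        ev_spont, schedule, diet=diet
    )
    hourly.to_csv(_out(out, "hourly.csv"), index=False, lineterminator="\n")

    # linear mixed models per microstructure parameter and cycle
    lmm_rows = []
    if len(meals_spont) and meals_spont["phase"].nunique() == 2:
        for value_col, label in LMM_PARAMETERS.items():
            for cycle in ("light", "dark"):
                sub = meals_spont.loc[meals_spont["cycle"] == cycle]
                if sub[value_col].dropna().empty:
                    continue
                res = fit_lmm(sub, value_col=value_col, parameter=f"{label}[{cycle}]")
                for phase in res.phases:
                    m, sem = res.emm[phase]
                    lmm_rows.append(
                        dict(parameter=label, cycle=cycle, phase=phase, emm=m, sem=sem,
                             contrast=res.contrast, se=res.se, pvalue=res.pvalue,
                             n_animals=res.n_animals, n_obs=res.n_obs,
                             fallback=res.fallback)
                    )
    lmm_cols = ["parameter", "cycle", "phase", "emm", "sem", "contrast", "se",
                "pvalue", "n_animals", "n_obs", "fallback"]
    pd.DataFrame(lmm_rows, columns=lmm_cols).to_csv(
        _out(out, "lmm_results.csv"), index=False, lineterminator="\n"
    )

    # classical tests: paired t on daily intake; Fisher on zero-intake hours
    test_rows = []
    zeros = zero_intake_hours(hourly, schedule)
    if len(hourly) and hourly["phase"].nunique() == 2:
        daily = (
            hourly.groupby(["animal_id", "phase", "day"])["intake_kcal"].sum()
            .groupby(["animal_id", "phase"]).mean().unstack("phase")
        )
        phases = list(daily.columns)
        if len(phases) == 2 and not daily.isna().any().any():
            try:
                t_res = paired_t(daily[phases[0]], daily[phases[1]])
                test_rows.append(
                    dict(test="paired_t", quantity="daily_intake_kcal",
                         group_a=phases[0], group_b=phases[1],
                         estimate=t_res.mean_difference, statistic=t_res.t,
                         pvalue=t_res.pvalue, n=t_res.n)
                )
            except Exception as exc:  # degenerate cohorts stay reportable
                log.warning("paired t on daily intake failed: %s", exc)
        if len(zeros):
            mean_zero = zeros.groupby("phase")["zero_total"].mean()
            if len(mean_zero) == 2:
                a, b = [int(round(v)) for v in mean_zero[phases].tolist()]
                table = ((b, 24 - b), (a, 24 - a))
                fisher = fisher_one_tailed(table, direction="greater")
                test_rows.append(
                    dict(test="fisher_one_tailed", quantity="zero_intake_hours",
                         group_a=phases[0], group_b=phases[1],
                         estimate=float(mean_zero[phases[1]] - mean_zero[phases[0]]),
                         statistic=np.nan, pvalue=fisher.pvalue, n=48)
                )
    test_cols = ["test", "quantity", "group_a", "group_b", "estimate",
                 "statistic", "pvalue", "n"]
    pd.DataFrame(test_rows, columns=test_cols).to_csv(
        _out(out, "tests.csv"), index=False, lineterminator="\n"
    )
    zeros.to_csv(_out(out, "zero_hours.csv"), index=False, lineterminator="\n")

    raster_export(meals_spont).to_csv(_out(out, "raster.csv"), index=False,
                                      lineterminator="\n")
    radial_export(hourly).to_csv(_out(out, "radial.csv"), index=False, lineterminator="\n")

    counts = {"meals_summarized": len(meals_spont), "lmm_fits": len(lmm_rows) // 2,
              "tests": len(test_rows)}
    log.info("summarize: %s", counts)
    return counts


def energy_stage(config: PipelineConfig) -> Dict[str, int]:
    out = Path(config.out_dir)
    manifest = read_manifest(out / "manifest.yaml")
    schedule = manifest.schedule
    samples = _attach_phase(
        read_calorimetry(out / "calorimetry.csv", manifest), manifest, schedule, "time"
    )
    activity = _attach_phase(
        read_activity(out / "activity.csv", manifest), manifest, schedule, "time"
    )
    summary = cycle_energy_summary(samples, activity, schedule)
    summary.to_csv(_out(out, "energy_summary.csv"), index=False, lineterminator="\n")
    counts = {"energy_rows": len(summary)}
    log.info("energy: %s", counts)
    return counts


def evoked_stage(config: PipelineConfig) -> Dict[str, int]:
    out = Path(config.out_dir)
    manifest = read_manifest(out / "manifest.yaml")
    schedule = manifest.schedule
    events = _attach_phase(read_events(out / "events.csv", manifest), manifest, schedule, "start")
    events["day"] = [schedule.day_index(t) for t in events["start"]]

    rows: List[dict] = []

    def _summarize(per, paradigm, window_h, value_col="intake_g"):
        contrast = None
        if per["phase"].nunique() == 2:
            try:
                contrast = evoked_contrast(per, paradigm, value_col=value_col)
            except Exception as exc:
                log.warning("evoked contrast for %s failed: %s", paradigm, exc)
        for phase, grp in per.groupby("phase"):
            rows.append(
                dict(paradigm=paradigm, window_h=window_h, phase=phase,
                     mean_g=grp[value_col].mean(), sd_g=grp[value_col].std(ddof=1),
                     n=len(grp),
                     percent_change=contrast.percent_change if contrast else np.nan,
                     pvalue=contrast.pvalue if contrast else np.nan)
            )

    # dark onset on spontaneous days of each phase
    parts = []
    for ph in manifest.phases():
        days = manifest.days(phase=ph, kind="spontaneous")
        sub = events.loc[(events["phase"] == ph) & events["day"].isin(days)]
        if sub.empty:
            continue
        res = dark_onset_response(sub, schedule, hours=4.0, days=days)
        parts.append(res.per_animal)
    if parts:
        combined = pd.concat(parts, ignore_index=True)
        _summarize(combined, "dark_onset", 4.0)
        _summarize(combined, "dark_onset_first_hour", 1.0, value_col="first_hour_g")

    # starve-refeed: second protocol day of each phase
    parts = []
    for ph in manifest.phases():
        days = manifest.days(phase=ph, kind="starve_refeed")
        if len(days) < 2:
            continue
        refeed_day = days[1]
        sub = events.loc[(events["phase"] == ph) & events["day"].isin(days)]
        if sub.empty:
            continue
        res = refeed_response(sub, schedule, refeed_day=refeed_day)
        parts.append(res.per_animal)
    if parts:
        combined = pd.concat(parts, ignore_index=True)
        for col, wh in (("intake_1h_g", 1.0), ("intake_4h_g", 4.0)):
            _summarize(combined, "starve_refeed", wh, value_col=col)

    # ghrelin and vehicle arms
    for kind in ("ghrelin", "vehicle"):
        parts = []
        for ph in manifest.phases():
            days = manifest.days(phase=ph, kind=kind)
            if not days:
                continue
            day = days[0]
            proto = manifest.protocol_of_day(day)
            sub = events.loc[(events["phase"] == ph) & (events["day"] == day)]
            if sub.empty:
                continue
            res = ghrelin_response(sub, schedule, proto.injection_time, day,
                                   window_h=proto.response_window_h, paradigm=kind)
            parts.append(res.per_animal)
        if parts:
            combined = pd.concat(parts, ignore_index=True)
            _summarize(combined, kind, 2.0)

    evoked_cols = ["paradigm", "window_h", "phase", "mean_g", "sd_g", "n",
                   "percent_change", "pvalue"]
    pd.DataFrame(rows, columns=evoked_cols).to_csv(
        _out(out, "evoked_results.csv"), index=False, lineterminator="\n"
    )
    counts = {"evoked_rows": len(rows)}
    log.info("evoked: %s", counts)
    return counts


def report_stage(config: PipelineConfig, stage_counts: Dict[str, Dict[str, int]]) -> Path:
    out = Path(config.out_dir)
    cfg_dict = asdict(config)
    digest = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode("utf-8")
    ).hexdigest()
    manifest = {
        "package": "mealscan",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": digest,
        "stages": stage_counts,
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    path = _out(out, "run_manifest.json")
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    log.info("report written to %s", path)
    return path


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in order and write the run manifest; deterministic
    given the master seed."""
    counts: Dict[str, Dict[str, int]] = {}
    counts["simulate"] = simulate_stage(config)
    counts["segment"] = segment_stage(config)
    counts["summarize"] = summarize_stage(config)
    counts["energy"] = energy_stage(config)
    counts["evoked"] = evoked_stage(config)
    return report_stage(config, counts)
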