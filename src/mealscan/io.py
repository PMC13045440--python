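"""Readers/writers for the four study artefacts.

Native metabolic-cage exports are proprietary, so the package defines a
small, bit-exact CSV dialect for each stream plus a YAML study manifest:

``events.csv``       ``animal_id,start,end,intake_g`` — one hopper
                     interaction per row, ISO-8601 local timestamps at 1-s
                     resolution, intake in grams with 2 decimals.
``calorimetry.csv``  ``animal_id,time,vo2_l_h,vco2_l_h`` — gas-exchange
                     scans in L/h with 4 decimals.
``activity.csv``     ``animal_id,time,axis,beam_index`` — infrared beam
                     breaks; timestamps carry milliseconds because breaks
                     within an ambulatory run are sub-second.
``manifest.yaml``    light schedule, diet energy density, animal ids,
                     per-day phase labels and protocol windows.

Durations are always derived (end − start), never stored.  All writers are
byte-stable: writing the same data twice yields identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import LightSchedule, ProtocolSpec
from .errors import ConfigurationError, ParseError, ValidationError

EVENT_COLUMNS = ["animal_id", "start", "end", "intake_g"]
CALORIMETRY_COLUMNS = ["animal_id", "time", "vo2_l_h", "vco2_l_h"]
ACTIVITY_COLUMNS = ["animal_id", "time", "axis", "beam_index"]

_TS_FMT = "%Y-%m-%dT%H:%M:%S"


# ---------------------------------------------------------------------------
# study manifest


@dataclass
class ObservationDay:
    """Phase label and protocol for one animal-day."""

    animal_id: str
    day: int
    phase: str  # baseline | kpc_d14 | sham
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec.spontaneous)


@dataclass
class StudyManifest:
    """Animals x observation days x protocols plus the housing constants."""

    animals: List[str]
    schedule: LightSchedule = field(default_factory=LightSchedule)
    diet_energy_density: float = 3.0
    observations: List[ObservationDay] = field(default_factory=list)

    def __post_init__(self):
        ids = set(self.animals)
        if len(ids) != len(self.animals):
            raise ConfigurationError("duplicate animal ids in manifest")
        for obs in self.observations:
            if obs.animal_id not in ids:
                raise ConfigurationError(f"observation references unknown animal {obs.animal_id!r}")
        if self.diet_energy_density <= 0:
            raise ConfigurationError("diet energy density must be positive")

    # -- queries ------------------------------------------------------------
    def phases(self) -> List[str]:
        seen: List[str] = []
        for obs in self.observations:
            if obs.phase not in seen:
                seen.append(obs.phase)
        return seen

    def days(self, phase: Optional[str] = None, kind: Optional[str] = None) -> List[int]:
        out = sorted(
            {
                obs.day
                for obs in self.observations
                if (phase is None or obs.phase == phase)
                and (kind is None or obs.protocol.kind == kind)
            }
        )
        return out

    def phase_of_day(self, day: int) -> Optional[str]:
        for obs in self.observations:
            if obs.day == day:
                return obs.phase
        return None

    def protocol_of_day(self, day: int) -> Optional[ProtocolSpec]:
        for obs in self.observations:
            if obs.day == day:
                return obs.protocol
        return None

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        def _proto(p: ProtocolSpec) -> dict:
            d: dict = {"kind": p.kind, "response_window_h": p.response_window_h}
            if p.food_removed is not None:
                d["food_removed"] = [t.strftime("%H:%M") for t in p.food_removed]
            if p.injection_time is not None:
                d["injection_time"] = p.injection_time.strftime("%H:%M")
            return d

        return {
            "light_on": self.schedule.light_on.strftime("%H:%M"),
            "light_off": self.schedule.light_off.strftime("%H:%M"),
            "diet_energy_density": float(self.diet_energy_density),
            "animals": list(self.animals),
            "observations": [
                {"animal": o.animal_id, "day": o.day, "phase": o.phase,
                 "protocol": _proto(o.protocol)}
                for o in self.observations
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "StudyManifest":
        try:
            schedule = LightSchedule(
                light_on=_parse_clock(data["light_on"]),
                light_off=_parse_clock(data["light_off"]),
            )
            observations = []
            for o in data.get("observations", []):
                p = o.get("protocol", {"kind": "spontaneous"})
                proto = ProtocolSpec(
                    kind=p["kind"],
                    food_removed=tuple(_parse_clock(t) for t in p["food_removed"])
                    if "food_removed" in p
                    else None,
                    injection_time=_parse_clock(p["injection_time"])
                    if "injection_time" in p
                    else None,
                    response_window_h=float(p.get("response_window_h", 4.0)),
                )
                observations.append(ObservationDay(o["animal"], int(o["day"]), o["phase"], proto))
            return cls(
                animals=list(data["animals"]),
                schedule=schedule,
                diet_energy_density=float(data["diet_energy_density"]),
                observations=observations,
            )
        except (KeyError, TypeError) as exc:
            raise ParseError(f"malformed manifest: {exc!r}") from exc


def _parse_clock(text: str) -> time:
    try:
        return datetime.strptime(text, "%H:%M").time()
    except ValueError as exc:
        raise ParseError(f"bad clock time {text!r}") from exc


def write_manifest(manifest: StudyManifest, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(manifest.to_dict(), sort_keys=False), encoding="utf-8"
    )


def read_manifest(path) -> StudyManifest:
    try:
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ParseError(f"could not parse manifest YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise ParseError("manifest must be a YAML mapping")
    return StudyManifest.from_dict(data)


# ---------------------------------------------------------------------------
# feeding events


def validate_events(events: pd.DataFrame, manifest: Optional[StudyManifest] = None) -> pd.DataFrame:
    """Validate and canonically sort an event table.

    Raises :class:`ValidationError` naming the offending row for end<start,
    negative intake, unknown animal ids and overlapping events.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValidationError(f"event table lacks columns {missing}")
    df = events.copy()
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    bad = df.index[df["end"] < df["start"]]
    if len(bad):
        raise ValidationError(f"event row {bad[0]}: end precedes start")
    bad = df.index[df["intake_g"] < 0]
    if len(bad):
        raise ValidationError(f"event row {bad[0]}: negative intake")
    if manifest is not None:
        known = set(manifest.animals)
        unknown = df.loc[~df["animal_id"].isin(known), "animal_id"]
        if len(unknown):
            raise ValidationError(
                f"event row {unknown.index[0]}: unknown animal id {unknown.iloc[0]!r}"
            )
    df = df.sort_values(["animal_id", "start", "end"], kind="mergesort").reset_index(drop=True)
    for animal, grp in df.groupby("animal_id", sort=False):
        overlap = grp["start"].values[1:] < grp["end"].values[:-1]
        if overlap.any():
            row = grp.index[1:][overlap][0]
            raise ValidationError(f"event row {row}: overlapping events for animal {animal!r}")
    return df


def write_events(events: pd.DataFrame, path) -> None:
    df = validate_events(events)
    out = pd.DataFrame(
        {
            "animal_id": df["animal_id"],
            "start": df["start"].dt.strftime(_TS_FMT),
            "end": df["end"].dt.strftime(_TS_FMT),
            "intake_g": [f"{v:.2f}" for v in df["intake_g"]],
        }
    )
    out.to_csv(path, index=False, lineterminator="\n")


def read_events(path, manifest: Optional[StudyManifest] = None) -> pd.DataFrame:
    df = _read_csv(path, EVENT_COLUMNS)
    if df.empty:
        return df.assign(
            start=pd.Series(dtype="datetime64[ns]"),
            end=pd.Series(dtype="datetime64[ns]"),
            intake_g=pd.Series(dtype=float),
        )[EVENT_COLUMNS]
    for col in ("start", "end"):
        try:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise ParseError(f"column {col!r}: unparseable timestamp ({exc})") from exc
    df["intake_g"] = _numeric(df, "intake_g")
    return validate_events(df, manifest)


# ---------------------------------------------------------------------------
# calorimetry


def write_calorimetry(samples: pd.DataFrame, path) -> None:
    missing = [c for c in CALORIMETRY_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"calorimetry table lacks columns {missing}")
    df = samples.sort_values(["animal_id", "time"], kind="mergesort")
    out = pd.DataFrame(
        {
            "animal_id": df["animal_id"],
            "time": pd.to_datetime(df["time"]).dt.strftime(_TS_FMT),
            "vo2_l_h": [f"{v:.4f}" for v in df["vo2_l_h"]],
            "vco2_l_h": [f"{v:.4f}" for v in df["vco2_l_h"]],
        }
    )
    out.to_csv(path, index=False, lineterminator="\n")


def read_calorimetry(
    path, manifest: Optional[StudyManifest] = None, units: str = "l_h"
) -> pd.DataFrame:
    """Read gas-exchange scans; ``units`` may be ``l_h`` or ``ml_h``."""
    if units not in ("l_h", "ml_h"):
        raise ConfigurationError(f"unknown gas units {units!r}")
    df = _read_csv(path, CALORIMETRY_COLUMNS)
    if df.empty:
        return df
    df["time"] = pd.to_datetime(df["time"], format="ISO8601")
    for col in ("vo2_l_h", "vco2_l_h"):
        df[col] = _numeric(df, col)
        if units == "ml_h":
            df[col] = df[col] / 1000.0
        bad = df.index[df[col] <= 0]
        if len(bad):
            raise ValidationError(f"calorimetry row {bad[0]}: non-positive {col}")
    if manifest is not None:
        unknown = df.loc[~df["animal_id"].isin(set(manifest.animals)), "animal_id"]
        if len(unknown):
            raise ValidationError(
                f"calorimetry row {unknown.index[0]}: unknown animal id {unknown.iloc[0]!r}"
            )
    return df.sort_values(["animal_id", "time"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# activity


def write_activity(stream: pd.DataFrame, path) -> None:
    missing = [c for c in ACTIVITY_COLUMNS if c not in stream.columns]
    if missing:
        raise ValidationError(f"activity table lacks columns {missing}")
    df = stream.sort_values(["animal_id", "time"], kind="mergesort")
    out = pd.DataFrame(
        {
            "animal_id": df["animal_id"],
            "time": pd.to_datetime(df["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f").str[:-3],
            "axis": df["axis"],
            "beam_index": df["beam_index"].astype(int),
        }
    )
    out.to_csv(path, index=False, lineterminator="\n")


def read_activity(path, manifest: Optional[StudyManifest] = None) -> pd.DataFrame:
    df = _read_csv(path, ACTIVITY_COLUMNS)
    if df.empty:
        return df
    df["time"] = pd.to_datetime(df["time"], format="ISO8601")
    bad_axis = df.index[~df["axis"].isin(["X", "Z"])]
    if len(bad_axis):
        raise ValidationError(f"activity row {bad_axis[0]}: axis must be X or Z")
    df["beam_index"] = _numeric(df, "beam_index").astype(int)
    bad = df.index[df["beam_index"] < 0]
    if len(bad):
        raise ValidationError(f"activity row {bad[0]}: negative beam index")
    if manifest is not None:
        unknown = df.loc[~df["animal_id"].isin(set(manifest.animals)), "animal_id"]
        if len(unknown):
            raise ValidationError(
                f"activity row {unknown.index[0]}: unknown animal id {unknown.iloc[0]!r}"
            )
    return df.sort_values(["animal_id", "time"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# helpers


def _read_csv(path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = path.open(encoding="utf-8").readline().strip()
    if header.split(",") != list(columns):
        raise ParseError(
            f"{path.name}: header {header!r} does not match dialect {','.join(columns)!r}"
        )
    try:
        df = pd.read_csv(path, dtype={"animal_id": str})
    except Exception as exc:  # malformed body
        raise ParseError(f"{path.name}: {exc}") from exc
    return df


def _numeric(df: pd.DataFrame, col: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[out.isna() & df[col].notna()]
    if len(bad):
        raise ParseError(f"column {col!r} row {bad[0]}: not numeric ({df[col][bad[0]]!r})")
    if out.isna().any():
        raise ParseError(f"column {col!r}: missing values")
    return out.astype(float)
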