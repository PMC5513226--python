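"""Data model and I/O for GPS fix tables and nest records.

Coordinates are planar meters (projected); no geodesy is performed anywhere
in the pipeline, since every downstream quantity is a Euclidean distance or
area. Timestamps are study-local naive datetimes. The "day" of a midnight
fix is the calendar day it closes: a roost location recorded at 00:00 of
date D describes the night of D-1 and is attributed to D-1 throughout.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("nestmove")


def get_logger(stage: str, bird_id: str | None = None) -> logging.LoggerAdapter:
    """Structured per-stage logger carrying bird context."""
    extra = {"stage": stage, "bird_id": bird_id if bird_id is not None else "-"}
    return logging.LoggerAdapter(logging.getLogger(f"nestmove.{stage}"), extra)


class SchemaError(ValueError):
    """A required column is missing or the file dialect is unusable."""


class ValidationError(ValueError):
    """A row violates a domain invariant (dates, fate labels, ...)."""


# Default fix schedules: clock hours at which the transmitter records.
# Hourly 0600-2000 plus one midnight roost fix, or 2-h increments 0600-2000
# plus midnight (9 fixes/day).
HOURLY_SCHEDULE: tuple[int, ...] = tuple(range(6, 21)) + (0,)
TWO_HOUR_SCHEDULE: tuple[int, ...] = tuple(range(6, 21, 2)) + (0,)

VALID_FATES = ("success", "fail", "unknown")


def fix_day(timestamp: dt.datetime) -> dt.date:
    """Calendar day a fix belongs to; midnight fixes close the previous day."""
    if timestamp.hour == 0 and timestamp.minute == 0 and timestamp.second == 0:
        return timestamp.date() - dt.timedelta(days=1)
    return timestamp.date()


@dataclass(frozen=True)
class GpsFix:
    bird_id: str
    timestamp: dt.datetime
    x: float
    y: float

    @property
    def is_roost(self) -> bool:
        return self.timestamp.hour == 0 and self.timestamp.minute == 0

    @property
    def day(self) -> dt.date:
        return fix_day(self.timestamp)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError(
                f"non-finite coordinates for {self.bird_id} at {self.timestamp}"
            )


@dataclass
class Track:
    """Time-ordered GPS fixes for one female, with the declared schedule."""

    bird_id: str
    fixes: list[GpsFix]
    schedule: tuple[int, ...] = HOURLY_SCHEDULE

    def __post_init__(self) -> None:
        if any(f.bird_id != self.bird_id for f in self.fixes):
            raise ValidationError(f"track {self.bird_id}: mixed bird ids")
        self.fixes = sorted(self.fixes, key=lambda f: f.timestamp)
        times = [f.timestamp for f in self.fixes]
        if len(set(times)) != len(times):
            raise ValidationError(f"track {self.bird_id}: duplicate timestamps")

    def __len__(self) -> int:
        return len(self.fixes)

    def to_frame(self) -> pd.DataFrame:
        """Vectorised view: timestamp, x, y, day, is_roost, seconds since start."""
        if not self.fixes:
            return pd.DataFrame(
                columns=["timestamp", "x", "y", "day", "is_roost", "t_s"]
            )
        ts = pd.to_datetime([f.timestamp for f in self.fixes])
        df = pd.DataFrame(
            {
                "timestamp": ts,
                "x": [f.x for f in self.fixes],
                "y": [f.y for f in self.fixes],
                "day": [f.day for f in self.fixes],
                "is_roost": [f.is_roost for f in self.fixes],
            }
        )
        df["t_s"] = (df["timestamp"] - df["timestamp"].iloc[0]).dt.total_seconds()
        return df

    @property
    def coords(self) -> np.ndarray:
        return np.array([[f.x, f.y] for f in self.fixes], dtype=float)

    @property
    def times_s(self) -> np.ndarray:
        t0 = self.fixes[0].timestamp
        return np.array(
            [(f.timestamp - t0).total_seconds() for f in self.fixes], dtype=float
        )


@dataclass
class NestAttempt:
    bird_id: str
    nest_x: float
    nest_y: float
    laying_onset: dt.date | None = None
    incubation_onset: dt.date | None = None
    fate: str = "unknown"
    attempt_index: int = 1

    def __post_init__(self) -> None:
        if self.fate not in VALID_FATES:
            raise ValidationError(
                f"nest for {self.bird_id}: fate {self.fate!r} not one of {VALID_FATES}"
            )
        if (
            self.laying_onset is not None
            and self.incubation_onset is not None
            and self.incubation_onset < self.laying_onset
        ):
            raise ValidationError(
                f"nest for {self.bird_id}: incubation onset "
                f"{self.incubation_onset} precedes laying onset {self.laying_onset}"
            )

    @property
    def nest(self) -> tuple[float, float]:
        return (self.nest_x, self.nest_y)


@dataclass
class AnalysisConfig:
    """Tunable parameters of the whole pipeline (all units metric).

    prenesting_days: length of the prenesting window counted back from the
        first laying day.
    incubation_radius_m: nest-centred radius within which every fix of a day
        must fall for that day to count as incubating.
    gps_exclusion_m: fixes closer than this to the nest are dropped from
        incubation-period distance summaries (GPS error floor).
    fixed_buffer_radii_m: radii of the fixed nest-centred circle buffers.
    population_incubation_distance_m: mean incubation distance per
        subspecies, the radius of the population-mean nest buffer.
    day_windows: inclusive days-before-laying windows for the contingency
        analysis.
    kernel_levels: isopleth probability-mass levels.
    """

    prenesting_days: int = 45
    incubation_radius_m: float = 50.0
    gps_exclusion_m: float = 10.0
    fixed_buffer_radii_m: tuple[float, ...] = (100.0, 500.0)
    population_incubation_distance_m: dict = field(
        default_factory=lambda: {"rio_grande": 70.82, "eastern": 55.24}
    )
    day_windows: tuple[tuple[int, int], ...] = ((1, 5), (6, 15), (16, 45))
    kernel_levels: tuple[float, ...] = (0.50, 0.75, 0.95, 0.99)
    schedule: str = "hourly"  # "hourly" or "two_hour"
    incubation_run_days: int = 2  # 1 reproduces the literal single-day rule
    laying_visit_radius_m: float | None = None  # defaults to incubation radius
    location_error_m: float = 10.0
    intersection_semantics: str = "closed_region"  # or "boundary_crossing"
    mean_distance_mode: str = "fixes"  # or "daily_means"
    contingency_unit: str = "segments"  # or "fixes"

    def __post_init__(self) -> None:
        if self.prenesting_days <= 0:
            raise ValidationError("prenesting_days must be positive")
        for r in (self.incubation_radius_m, *self.fixed_buffer_radii_m):
            if r <= 0:
                raise ValidationError("all radii must be positive")
        for lev in self.kernel_levels:
            if not 0.0 < lev < 1.0:
                raise ValidationError(f"kernel level {lev} outside (0,1)")
        spans = sorted(self.day_windows)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if a1 >= b0:
                raise ValidationError(f"day windows overlap: {spans}")
        if self.schedule not in ("hourly", "two_hour"):
            raise ValidationError(f"unknown schedule {self.schedule!r}")

    @property
    def schedule_hours(self) -> tuple[int, ...]:
        return HOURLY_SCHEDULE if self.schedule == "hourly" else TWO_HOUR_SCHEDULE

    @property
    def visit_radius_m(self) -> float:
        if self.laying_visit_radius_m is not None:
            return self.laying_visit_radius_m
        return self.incubation_radius_m

    def to_file(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["fixed_buffer_radii_m"] = list(self.fixed_buffer_radii_m)
        d["day_windows"] = [list(w) for w in self.day_windows]
        d["kernel_levels"] = list(self.kernel_levels)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "fixed_buffer_radii_m" in d:
            d["fixed_buffer_radii_m"] = tuple(d["fixed_buffer_radii_m"])
        if "day_windows" in d:
            d["day_windows"] = tuple(tuple(w) for w in d["day_windows"])
        if "kernel_levels" in d:
            d["kernel_levels"] = tuple(d["kernel_levels"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

DEFAULT_FIX_SCHEMA: Mapping[str, str] = {
    "bird_id": "bird_id",
    "timestamp": "timestamp",
    "x": "x_m",
    "y": "y_m",
}


@dataclass
class RowError:
    line: int
    message: str


def read_fixes(
    path: str | Path,
    schema: Mapping[str, str] = DEFAULT_FIX_SCHEMA,
    delimiter: str = ",",
    schedule: Sequence[int] = HOURLY_SCHEDULE,
) -> tuple[list[Track], list[RowError]]:
    """Read a delimited fix table into per-bird Tracks.

    Returns one time-sorted ``Track`` per bird plus a list of rejected rows
    (unparseable timestamp or non-finite coordinate) with 1-based file line
    numbers. A missing column raises :class:`SchemaError`.
    """
    log = get_logger("tracks_io")
    df = pd.read_csv(path, delimiter=delimiter, dtype=str)
    missing = [col for col in schema.values() if col not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    errors: list[RowError] = []
    fixes_by_bird: dict[str, list[GpsFix]] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            ts = pd.Timestamp(row[schema["timestamp"]]).to_pydatetime()
            x = float(row[schema["x"]])
            y = float(row[schema["y"]])
            fx = GpsFix(str(row[schema["bird_id"]]), ts, x, y)
        except (ValueError, ValidationError, TypeError) as exc:
            errors.append(RowError(line, str(exc)))
            log.warning("line %d rejected: %s", line, exc)
            continue
        fixes_by_bird.setdefault(fx.bird_id, []).append(fx)

    tracks = [
        Track(bird, fixes, schedule=tuple(schedule))
        for bird, fixes in fixes_by_bird.items()
    ]
    log.info("read %d tracks, %d row errors from %s", len(tracks), len(errors), path)
    return tracks, errors


def write_fixes(tracks: Iterable[Track], path: str | Path) -> None:
    rows = [
        {
            "bird_id": f.bird_id,
            "timestamp": f.timestamp.isoformat(),
            "x_m": f"{f.x:.6f}",
            "y_m": f"{f.y:.6f}",
        }
        for tr in tracks
        for f in tr.fixes
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_nests(path: str | Path, delimiter: str = ",") -> list[NestAttempt]:
    """Read the nest table; attempts grouped per bird, indexed by laying date."""
    df = pd.read_csv(path, delimiter=delimiter, dtype=str)
    required = ["bird_id", "nest_x_m", "nest_y_m"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    def parse_date(v) -> dt.date | None:
        if v is None or (isinstance(v, float) and np.isnan(v)) or v in ("", "NA"):
            return None
        return pd.Timestamp(v).date()

    attempts: list[NestAttempt] = []
    for _, row in df.iterrows():
        attempts.append(
            NestAttempt(
                bird_id=str(row["bird_id"]),
                nest_x=float(row["nest_x_m"]),
                nest_y=float(row["nest_y_m"]),
                laying_onset=parse_date(row.get("laying_onset")),
                incubation_onset=parse_date(row.get("incubation_onset")),
                fate=str(row.get("fate", "unknown")) if pd.notna(row.get("fate")) else "unknown",
            )
        )
    # attempt_index by laying date within bird
    by_bird: dict[str, list[NestAttempt]] = {}
    for a in attempts:
        by_bird.setdefault(a.bird_id, []).append(a)
    out: list[NestAttempt] = []
    for bird, alist in by_bird.items():
        alist.sort(key=lambda a: (a.laying_onset or dt.date.max))
        for i, a in enumerate(alist, start=1):
            a.attempt_index = i
            out.append(a)
    return out


def write_nests(nests: Iterable[NestAttempt], path: str | Path) -> None:
    rows = [
        {
            "bird_id": a.bird_id,
            "attempt": a.attempt_index,
            "nest_x_m": f"{a.nest_x:.6f}",
            "nest_y_m": f"{a.nest_y:.6f}",
            "laying_onset": a.laying_onset.isoformat() if a.laying_onset else "",
            "incubation_onset": (
                a.incubation_onset.isoformat() if a.incubation_onset else ""
            ),
            "fate": a.fate,
        }
        for a in nests
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Schedule validation
# ---------------------------------------------------------------------------


@dataclass
class ScheduleReport:
    per_day: pd.DataFrame  # columns: day, expected, observed, complete
    proportion_complete: float
    unexpected: int  # fixes at clock hours outside the declared schedule


def validate_schedule(
    track: Track, expected: Sequence[int] | None = None
) -> ScheduleReport:
    """Compare observed fixes per day against the declared schedule.

    Report-only: counts observed vs expected fixes on every day the track
    spans (a midnight fix counts toward the day it closes) and the
    proportion of fully sampled days.
    """
    if not track.fixes:
        raise ValidationError(f"track {track.bird_id} is empty")
    hours = tuple(expected) if expected is not None else track.schedule
    n_expected = len(set(hours))
    df = track.to_frame()
    unexpected = int((~df["timestamp"].dt.hour.isin(hours)).sum())
    counts = (
        df[df["timestamp"].dt.hour.isin(hours)]
        .groupby("day")["timestamp"]
        .nunique()
        .rename("observed")
        .reset_index()
    )
    if counts.empty:
        counts = pd.DataFrame({"day": sorted(df["day"].unique()), "observed": 0})
    counts["expected"] = n_expected
    counts["complete"] = counts["observed"] >= counts["expected"]
    prop = float(counts["complete"].mean()) if len(counts) and n_expected else 0.0
    return ScheduleReport(per_day=counts, proportion_complete=prop, unexpected=unexpected)
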