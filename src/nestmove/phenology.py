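"""Reproductive-phase delineation from movement.

Three phases are carved out of each female's track relative to her nest:

* prenesting — the ``prenesting_days`` (default 45) days before the first
  laying day, indexed as days-before-laying 1..45 counting back from laying;
* laying — daily trips to the nest while roosting elsewhere;
* incubation — from the first day on which every fix of the day lies within
  the incubation radius (default 50 m) of the nest.

All windows are half-open ``[start, end)`` at day resolution.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks_io import (
    AnalysisConfig,
    NestAttempt,
    Track,
    ValidationError,
    get_logger,
)

PHASES = ("prenesting", "laying", "incubation", "other")


@dataclass
class PhaseLabels:
    bird_id: str
    laying_onset: dt.date
    incubation_onset: dt.date
    prenesting_start: dt.date
    frame: pd.DataFrame  # per fix: timestamp, day, phase, days_before_laying

    @property
    def phase(self) -> pd.Series:
        return self.frame["phase"]

    @property
    def days_before_laying(self) -> pd.Series:
        return self.frame["days_before_laying"]


def _daily_within(track: Track, nest: tuple[float, float], radius: float) -> pd.DataFrame:
    """Per tracked day: whether every fix of the day lies within radius of nest."""
    df = track.to_frame()
    d = np.hypot(df["x"] - nest[0], df["y"] - nest[1])
    df = df.assign(within=d <= radius, dist=d)
    return df.groupby("day").agg(
        all_within=("within", "all"),
        any_within=("within", "any"),
        n=("within", "size"),
    )


def detect_incubation_onset(
    track: Track,
    nest: tuple[float, float],
    radius: float = 50.0,
    min_run_days: int = 2,
) -> dt.date | None:
    """Earliest day on which all fixes lie within ``radius`` of the nest.

    The day must open a run of at least ``min_run_days`` consecutive
    all-within days; ``min_run_days=1`` reproduces the literal single-day
    rule, the default of 2 guards against one-off low-movement days.
    Returns ``None`` when no qualifying day exists.
    """
    if not track.fixes:
        raise ValidationError(f"track {track.bird_id} is empty")
    daily = _daily_within(track, nest, radius)
    days = list(daily.index)
    flags = daily["all_within"].to_numpy()
    for i, day in enumerate(days):
        if not flags[i]:
            continue
        run = 1
        while (
            i + run < len(days)
            and flags[i + run]
            and (days[i + run] - days[i + run - 1]).days == 1
        ):
            run += 1
        if run >= min_run_days:
            return day
    return None


def detect_laying_onset(
    track: Track,
    nest: tuple[float, float],
    visit_radius: float,
    incubation_onset: dt.date,
) -> dt.date:
    """First day of the laying period preceding a known incubation onset.

    A laying day shows the visit signature: at least one non-midnight fix
    within ``visit_radius`` of the nest while the midnight roost fix lies
    outside it. Laying is the run of consecutive signature days ending on
    the day before incubation begins; when no such run exists the laying
    onset collapses onto the incubation onset (logged).
    """
    log = get_logger("phenology", track.bird_id)
    df = track.to_frame()
    df = df[df["day"] < incubation_onset]
    if df.empty:
        log.info("no pre-incubation fixes; laying onset = incubation onset")
        return incubation_onset
    d = np.hypot(df["x"] - nest[0], df["y"] - nest[1])
    df = df.assign(within=d <= visit_radius)
    by_day = df.groupby("day").apply(
        lambda g: bool(
            g.loc[~g["is_roost"], "within"].any()
            and not g.loc[g["is_roost"], "within"].any()
        ),
        include_groups=False,
    )
    visit_days = {day for day, flag in by_day.items() if flag}
    if not visit_days:
        log.info("no laying-visit signature; laying onset = incubation onset")
        return incubation_onset
    day = incubation_onset - dt.timedelta(days=1)
    if day not in visit_days:
        log.info("visit runs do not touch incubation; laying onset = incubation onset")
        return incubation_onset
    while day - dt.timedelta(days=1) in visit_days:
        day -= dt.timedelta(days=1)
    return day


def delineate_phases(
    track: Track, nest: NestAttempt, config: AnalysisConfig | None = None
) -> PhaseLabels:
    """Tag every fix with its reproductive phase and days-before-laying index.

    Onsets come from the nest record when present, otherwise from the
    movement detectors above. Prenesting is ``[laying − prenesting_days,
    laying)``; fixes outside every window are tagged ``other``.
    """
    config = config or AnalysisConfig()
    log = get_logger("phenology", track.bird_id)

    incubation_onset = nest.incubation_onset
    if incubation_onset is None:
        incubation_onset = detect_incubation_onset(
            track,
            nest.nest,
            radius=config.incubation_radius_m,
            min_run_days=config.incubation_run_days,
        )
        if incubation_onset is None:
            raise ValidationError(
                f"bird {track.bird_id}: incubation onset not detectable"
            )
    laying_onset = nest.laying_onset
    if laying_onset is None:
        laying_onset = detect_laying_onset(
            track, nest.nest, config.visit_radius_m, incubation_onset
        )

    prenesting_start = laying_onset - dt.timedelta(days=config.prenesting_days)

    df = track.to_frame()
    days = df["day"]
    phase = np.full(len(df), "other", dtype=object)
    phase[(days >= prenesting_start) & (days < laying_onset)] = "prenesting"
    phase[(days >= laying_onset) & (days < incubation_onset)] = "laying"
    # incubation runs from onset through the last day of the consecutive
    # all-within run (a failed female resumes ranging afterwards -> other)
    daily = _daily_within(track, nest.nest, config.incubation_radius_m)
    inc_end = incubation_onset
    prev = None
    for day in sorted(daily.index):
        if day < incubation_onset:
            continue
        if not daily.loc[day, "all_within"]:
            break
        if prev is not None and (day - prev).days != 1:
            break
        inc_end = day + dt.timedelta(days=1)
        prev = day
    phase[(days >= incubation_onset) & (days < inc_end)] = "incubation"

    dbl = np.where(
        phase == "prenesting",
        [(laying_onset - d).days for d in days],
        0,
    ).astype(int)
    frame = df.assign(phase=phase, days_before_laying=dbl)

    n_pre_days = frame.loc[frame["phase"] == "prenesting", "day"].nunique()
    if n_pre_days == 0:
        log.warning("track covers no prenesting day")
    log.info(
        "phases: laying=%s incubation=%s prenest days=%d",
        laying_onset,
        incubation_onset,
        n_pre_days,
    )
    return PhaseLabels(
        bird_id=track.bird_id,
        laying_onset=laying_onset,
        incubation_onset=incubation_onset,
        prenesting_start=prenesting_start,
        frame=frame,
    )


def write_phases(labels: PhaseLabels, path) -> None:
    out = labels.frame[["day", "phase", "days_before_laying"]].copy()
    out.insert(0, "bird_id", labels.bird_id)
    out.to_csv(path, index=False)
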