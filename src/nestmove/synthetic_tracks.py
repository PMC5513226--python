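"""Truth-tagged synthetic GPS tracks emulating the study's monitoring design.

One simulated female is a biased correlated random walk (gamma step lengths,
wrapped-Cauchy turning angles, linear attraction toward a range centre)
sampled on the transmitter schedule (hourly 0600-2000 plus one midnight
roost fix by default; 2-h increments also supported), with a phase-structured
reproductive timeline:

* prenesting — ``prenesting_days`` days of ranging; under the
  ``habitat_sampling='sampling'`` switch the female additionally visits the
  future nest area with a per-day probability that ramps up toward laying
  (the behaviour whose movement signature the inference layer is built to
  detect; ``'none'`` is the no-sampling null world);
* laying — one daytime nest visit per day, midnight roost elsewhere;
* incubation — every fix is the nest plus GPS noise, ending in hatch or a
  daily-hazard failure.

Every fix carries isotropic Gaussian GPS error ``gps_sigma``. Each bird
draws from its own named random stream spawned from the master seed, so
per-bird output is reproducible regardless of simulation order.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .tracks_io import (
    HOURLY_SCHEDULE,
    GpsFix,
    NestAttempt,
    Track,
    ValidationError,
    write_fixes,
    write_nests,
)


@dataclass
class SimConfig:
    n_birds: int = 21
    schedule: tuple[int, ...] = HOURLY_SCHEDULE
    prenesting_days: int = 45
    laying_days_mean: float = 12.0
    laying_days_sd: float = 2.0
    incubation_days_mean: float = 27.0
    incubation_days_sd: float = 1.0
    step_shape: float = 2.0  # gamma shape of hourly step length
    step_scale: float = 90.0  # gamma scale (m); mean step = shape * scale
    turn_rho: float = 0.4  # wrapped-Cauchy concentration of turning angles
    attraction: float = 0.08  # per-step pull toward the range centre
    n_roosts: int = 3
    roost_spread: float = 400.0  # roost-site scatter around the centre (m)
    nest_offset_median: float = 700.0  # lognormal median nest-centre distance
    nest_offset_sigma: float = 0.5  # lognormal shape
    habitat_sampling: str = "none"  # "none" | "sampling"
    sampling_rate: float = 0.2  # mean prenesting nest-visit probability/day
    gps_sigma: float = 10.0  # GPS error SD per axis (m)
    daily_failure_prob: float = 0.08  # incubation failure hazard per day
    capture_delay_days: int = 0  # late capture truncates prenesting coverage
    start_date: dt.date = dt.date(2023, 3, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("step_shape", "step_scale", "roost_spread", "gps_sigma"):
            if getattr(self, name) < 0 or (
                name in ("step_shape", "step_scale") and getattr(self, name) <= 0
            ):
                raise ValidationError(f"{name} must be positive")
        if not 0.0 <= self.turn_rho < 1.0:
            raise ValidationError("turn_rho must be in [0, 1)")
        if self.habitat_sampling not in ("none", "sampling"):
            raise ValidationError(f"unknown sampling mode {self.habitat_sampling!r}")
        if not self.schedule:
            raise ValidationError("schedule is empty")


@dataclass
class TruthRecord:
    bird_id: str
    nest: tuple[float, float]
    laying_onset: dt.date
    incubation_onset: dt.date
    fate: str
    habitat_sampling: bool
    daily_min_distance: dict = field(default_factory=dict)  # day -> true min (m)


def wrapped_cauchy_turns(rng: np.random.Generator, rho: float, n: int) -> np.ndarray:
    """Turning angles in (-pi, pi] from a wrapped Cauchy centred on zero."""
    u = rng.random(n)
    if rho == 0.0:
        return (u - 0.5) * 2.0 * np.pi
    return 2.0 * np.arctan(((1 - rho) / (1 + rho)) * np.tan(np.pi * (u - 0.5)))


class _Walker:
    """Biased correlated random walk state (true positions, no GPS noise)."""

    def __init__(self, center: np.ndarray, cfg: SimConfig, rng: np.random.Generator):
        self.center = center
        self.cfg = cfg
        self.rng = rng
        self.pos = center.copy()
        self.heading = rng.uniform(-np.pi, np.pi)

    def step(self) -> np.ndarray:
        self.heading += float(wrapped_cauchy_turns(self.rng, self.cfg.turn_rho, 1)[0])
        length = self.rng.gamma(self.cfg.step_shape, self.cfg.step_scale)
        move = length * np.array([math.cos(self.heading), math.sin(self.heading)])
        new = self.pos + move + self.cfg.attraction * (self.center - self.pos)
        if self.cfg.attraction > 0:
            actual = new - self.pos
            if np.hypot(*actual) > 0:
                self.heading = math.atan2(actual[1], actual[0])
        self.pos = new
        return self.pos.copy()


def _visit_probability(day_before_laying: int, cfg: SimConfig) -> float:
    """Per-day nest-visit probability under the sampling hypothesis.

    Linear ramp toward laying with across-day mean ~= sampling_rate.
    """
    d = cfg.prenesting_days
    return min(1.0, cfg.sampling_rate * 2.0 * (d + 1 - day_before_laying) / (d + 1))


def simulate_female(
    cfg: SimConfig, rng: np.random.Generator, bird_id: str = "S001"
) -> tuple[Track, TruthRecord]:
    """Simulate one female's full reproductive track with ground truth."""
    day_hours = sorted(h for h in set(cfg.schedule) if h != 0)
    has_midnight = 0 in cfg.schedule
    if not day_hours and not has_midnight:
        raise ValidationError("schedule has no usable hours")

    center = np.zeros(2)
    theta = rng.uniform(0, 2 * np.pi)
    offset = cfg.nest_offset_median * np.exp(rng.normal(0.0, cfg.nest_offset_sigma))
    nest = center + offset * np.array([math.cos(theta), math.sin(theta)])
    roosts = []
    while len(roosts) < cfg.n_roosts:
        cand = center + rng.normal(0.0, cfg.roost_spread, 2)
        if np.hypot(*(cand - nest)) > 150.0:
            roosts.append(cand)
    roosts = np.array(roosts)

    n_laying = int(np.clip(round(rng.normal(cfg.laying_days_mean, cfg.laying_days_sd)), 8, 16))
    n_incubation = int(
        np.clip(round(rng.normal(cfg.incubation_days_mean, cfg.incubation_days_sd)), 22, 30)
    )
    fate = "success"
    for k in range(3, n_incubation + 1):  # hazard starts after onset settles
        if rng.random() < cfg.daily_failure_prob:
            n_incubation, fate = k, "fail"
            break

    laying_onset = cfg.start_date + dt.timedelta(days=cfg.prenesting_days)
    incubation_onset = laying_onset + dt.timedelta(days=n_laying)
    first_day = cfg.start_date + dt.timedelta(days=cfg.capture_delay_days)
    last_day = incubation_onset + dt.timedelta(days=n_incubation - 1)

    walker = _Walker(center, cfg, rng)
    for _ in range(150):  # burn-in to the walk's stationary regime
        walker.step()

    fixes: list[GpsFix] = []
    truth_daily_min: dict[dt.date, float] = {}

    def emit(ts: dt.datetime, true_pos: np.ndarray) -> None:
        noisy = true_pos + rng.normal(0.0, cfg.gps_sigma, 2)
        fixes.append(GpsFix(bird_id, ts, float(noisy[0]), float(noisy[1])))

    day = first_day
    while day <= last_day:
        in_prenest = day < laying_onset
        in_laying = laying_onset <= day < incubation_onset
        in_incubation = day >= incubation_onset
        day_mins: list[float] = []

        visit_hour = None
        if in_laying:
            visit_hour = int(rng.choice(day_hours))
        elif in_prenest and cfg.habitat_sampling == "sampling":
            dbl = (laying_onset - day).days
            if dbl <= cfg.prenesting_days and rng.random() < _visit_probability(dbl, cfg):
                visit_hour = int(rng.choice(day_hours))

        for hour in day_hours:
            ts = dt.datetime.combine(day, dt.time(hour))
            if in_incubation:
                true_pos = nest
            elif hour == visit_hour and in_laying:
                # egg deposition: the female is at the nest itself
                walker.pos = nest.copy()
                true_pos = walker.pos
            elif hour == visit_hour:
                # prenesting habitat-sampling visit to the nest area
                walker.pos = nest + rng.normal(0.0, 15.0, 2)
                true_pos = walker.pos
            else:
                true_pos = walker.step()
            day_mins.append(float(np.hypot(*(true_pos - nest))))
            emit(ts, np.asarray(true_pos, float))

        if has_midnight:
            ts = dt.datetime.combine(day + dt.timedelta(days=1), dt.time(0))
            if in_incubation:
                true_pos = nest
            else:
                true_pos = roosts[np.argmin(np.hypot(*(roosts - walker.pos).T))]
                walker.pos = np.asarray(true_pos, float).copy()
            day_mins.append(float(np.hypot(*(np.asarray(true_pos) - nest))))
            emit(ts, np.asarray(true_pos, float))

        if day_mins:
            truth_daily_min[day] = min(day_mins)
        day += dt.timedelta(days=1)

    track = Track(bird_id, fixes, schedule=tuple(cfg.schedule))
    truth = TruthRecord(
        bird_id=bird_id,
        nest=(float(nest[0]), float(nest[1])),
        laying_onset=laying_onset,
        incubation_onset=incubation_onset,
        fate=fate,
        habitat_sampling=cfg.habitat_sampling == "sampling",
        daily_min_distance=truth_daily_min,
    )
    return track, truth


def simulate_population(
    cfg: SimConfig, outdir: str | Path | None = None
) -> tuple[list[Track], list[TruthRecord]]:
    """Independent females from per-bird streams spawned off the master seed.

    With ``outdir`` set, writes ``fixes.csv`` / ``nests.csv`` (the pipeline's
    input dialects) and ``truth.csv``; identical seeds give byte-identical
    files.
    """
    if cfg.n_birds < 1:
        raise ValidationError("n_birds must be >= 1")
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_birds)
    tracks: list[Track] = []
    truths: list[TruthRecord] = []
    for i, ss in enumerate(streams):
        bird_id = f"S{i + 1:03d}"
        tr, tru = simulate_female(cfg, np.random.default_rng(ss), bird_id)
        tracks.append(tr)
        truths.append(tru)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fixes(tracks, outdir / "fixes.csv")
        nests = [
            NestAttempt(
                bird_id=t.bird_id,
                nest_x=t.nest[0],
                nest_y=t.nest[1],
                laying_onset=t.laying_onset,
                incubation_onset=t.incubation_onset,
                fate=t.fate,
            )
            for t in truths
        ]
        write_nests(nests, outdir / "nests.csv")
        pd.DataFrame(
            [
                {
                    "bird_id": t.bird_id,
                    "nest_x_m": f"{t.nest[0]:.6f}",
                    "nest_y_m": f"{t.nest[1]:.6f}",
                    "laying_onset": t.laying_onset.isoformat(),
                    "incubation_onset": t.incubation_onset.isoformat(),
                    "fate": t.fate,
                    "habitat_sampling": int(t.habitat_sampling),
                }
                for t in truths
            ]
        ).to_csv(outdir / "truth.csv", index=False)
    return tracks, truths


def nests_from_truth(truths: list[TruthRecord], known_onsets: bool = True) -> list[NestAttempt]:
    """Nest records as the field data would carry them.

    ``known_onsets=False`` blanks the onset dates so the movement detectors
    must recover them.
    """
    return [
        NestAttempt(
            bird_id=t.bird_id,
            nest_x=t.nest[0],
            nest_y=t.nest[1],
            laying_onset=t.laying_onset if known_onsets else None,
            incubation_onset=t.incubation_onset if known_onsets else None,
            fate=t.fate,
        )
        for t in truths
    ]
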