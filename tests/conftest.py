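import datetime as dt

import numpy as np
import pytest

from nestmove.synthetic_tracks import SimConfig, simulate_population
from nestmove.tracks_io import GpsFix, HOURLY_SCHEDULE, Track


@pytest.fixture(scope="session")
def small_population():
    """Four no-sampling birds on the default schedule, fixed seed."""
    cfg = SimConfig(n_birds=4, seed=42)
    return simulate_population(cfg)


def make_track(
    bird_id: str,
    positions,
    start: dt.datetime = dt.datetime(2023, 3, 1, 6),
    step_hours: float = 1.0,
    schedule=HOURLY_SCHEDULE,
) -> Track:
    """Track from a bare position sequence at a fixed time step."""
    fixes = [
        GpsFix(
            bird_id,
            start + dt.timedelta(hours=i * step_hours),
            float(x),
            float(y),
        )
        for i, (x, y) in enumerate(positions)
    ]
    return Track(bird_id, fixes, schedule=schedule)


def make_scheduled_track(bird_id: str, day_positions: dict) -> Track:
    """Track from {date: position or {hour: position}} on the hourly schedule.

    A scalar position is used for every scheduled fix of that day; the
    midnight fix is stamped 00:00 of the following date (it closes the day).
    """
    fixes = []
    for day, spec in sorted(day_positions.items()):
        for hour in sorted(h for h in HOURLY_SCHEDULE if h != 0):
            pos = spec[hour] if isinstance(spec, dict) else spec
            fixes.append(
                GpsFix(
                    bird_id,
                    dt.datetime.combine(day, dt.time(hour)),
                    float(pos[0]),
                    float(pos[1]),
                )
            )
        pos = spec[0] if isinstance(spec, dict) else spec
        fixes.append(
            GpsFix(
                bird_id,
                dt.datetime.combine(day + dt.timedelta(days=1), dt.time(0)),
                float(pos[0]),
                float(pos[1]),
            )
        )
    return Track(bird_id, fixes)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
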