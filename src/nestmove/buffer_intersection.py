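"""Nest-associated buffers and path-segment intersection classification.

Five individual-specific regions around each nest:

1. ``kernel95_equiv_circle`` — circle whose radius gives the same area as
   the female's 95% incubation kernel (equivalent radius r = sqrt(A/pi));
2. ``kernel75_polygon`` — the 75% incubation-kernel isopleth itself;
3. ``mean_incubation_circle`` — circle at the population mean incubation
   distance (Rio Grande 70.82 m, Eastern 55.24 m by default);
4. ``fixed_100m`` and 5. ``fixed_500m`` — fixed-radius circles.

Every consecutive-fix path segment within the prenesting window is scored
0/1 against each region. Default semantics: a segment intersects if any
point of the closed segment lies in the closed region (crossing OR full
containment — a path wholly inside a nest buffer is an interaction);
boundary-crossing-only semantics is available via config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon

from .phenology import PhaseLabels
from .range_estimation import IsoplethPolygon, UDGrid, extract_isopleth
from .tracks_io import AnalysisConfig, Track, ValidationError, get_logger

REGION_ORDER = (
    "kernel95_equiv_circle",
    "kernel75_polygon",
    "mean_incubation_circle",
    "fixed_100m",
    "fixed_500m",
)


@dataclass(frozen=True)
class CircleRegion:
    center: tuple[float, float]
    radius: float


@dataclass(frozen=True)
class PolygonRegion:
    polygon: object  # shapely (Multi)Polygon


@dataclass
class BufferSet:
    bird_id: str
    regions: dict  # label -> CircleRegion | PolygonRegion

    @property
    def labels(self) -> list[str]:
        return [r for r in REGION_ORDER if r in self.regions]


def equivalent_radius(area_m2: float) -> float:
    """Radius of the circle with the given area: r = sqrt(A / pi)."""
    if area_m2 <= 0:
        raise ValidationError(f"area must be positive, got {area_m2}")
    return math.sqrt(area_m2 / math.pi)


def build_buffers(
    nest: tuple[float, float],
    incubation_ud: UDGrid | None,
    subspecies: str,
    config: AnalysisConfig | None = None,
) -> BufferSet:
    """Assemble the five nest-associated regions for one female.

    Without an incubation UD only the three fixed-radius/distance circles
    are built (logged).
    """
    config = config or AnalysisConfig()
    log = get_logger("buffer_intersection")
    if subspecies not in config.population_incubation_distance_m:
        raise ValidationError(f"unknown subspecies {subspecies!r}")
    regions: dict = {
        "mean_incubation_circle": CircleRegion(
            nest, config.population_incubation_distance_m[subspecies]
        ),
    }
    for r in config.fixed_buffer_radii_m:
        regions[f"fixed_{int(r)}m"] = CircleRegion(nest, float(r))
    if incubation_ud is None:
        log.warning("incubation UD missing: kernel regions omitted")
    else:
        iso95 = extract_isopleth(incubation_ud, 0.95)
        regions["kernel95_equiv_circle"] = CircleRegion(
            nest, equivalent_radius(iso95.area_ha * 1e4)
        )
        iso75 = extract_isopleth(incubation_ud, 0.75)
        regions["kernel75_polygon"] = PolygonRegion(iso75.geometry)
    return BufferSet(bird_id="", regions=regions)


def _point_segment_distance(
    p: np.ndarray, a: np.ndarray, b: np.ndarray
) -> float:
    """Distance from point p to the closed segment ab."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.hypot(*(p - a)))
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.hypot(*(p - (a + t * ab))))


def segment_intersects(
    a: tuple[float, float],
    b: tuple[float, float],
    region: CircleRegion | PolygonRegion,
    semantics: str = "closed_region",
) -> bool:
    """Does the closed segment a-b interact with the region?

    closed_region: any point of the segment inside or on the region.
    boundary_crossing: the segment touches the region's boundary curve.
    """
    pa, pb = np.asarray(a, float), np.asarray(b, float)
    if isinstance(region, CircleRegion):
        c = np.asarray(region.center, float)
        dmin = _point_segment_distance(c, pa, pb)
        if semantics == "closed_region":
            return dmin <= region.radius
        dmax = max(float(np.hypot(*(pa - c))), float(np.hypot(*(pb - c))))
        return dmin <= region.radius <= dmax
    geom = region.polygon
    if pa[0] == pb[0] and pa[1] == pb[1]:
        seg = Point(pa)
    else:
        seg = LineString([pa, pb])
    if semantics == "closed_region":
        return bool(seg.intersects(geom))
    return bool(seg.intersects(geom.boundary))


def _circle_flags(
    ax: np.ndarray,
    ay: np.ndarray,
    bx: np.ndarray,
    by: np.ndarray,
    region: CircleRegion,
    semantics: str,
) -> np.ndarray:
    """Vectorised segment-circle interaction over parallel endpoint arrays."""
    cx, cy = region.center
    abx, aby = bx - ax, by - ay
    denom = abx**2 + aby**2
    t = np.where(denom > 0, ((cx - ax) * abx + (cy - ay) * aby) / np.where(denom > 0, denom, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    dmin = np.hypot(cx - (ax + t * abx), cy - (ay + t * aby))
    if semantics == "closed_region":
        return dmin <= region.radius
    dmax = np.maximum(np.hypot(ax - cx, ay - cy), np.hypot(bx - cx, by - cy))
    return (dmin <= region.radius) & (region.radius <= dmax)


def classify_segments(
    track: Track,
    phase: PhaseLabels,
    buffers: BufferSet,
    semantics: str = "closed_region",
) -> pd.DataFrame:
    """0/1 intersection flags for every prenesting path segment.

    Segments join consecutive fixes whose days are both tagged prenesting;
    segments spanning a phase boundary are dropped. A segment's
    days-before-laying index is that of its starting fix. Zero-length
    segments are classified by point containment.
    """
    df = phase.frame
    labels = buffers.labels
    is_pre = (df["phase"] == "prenesting").to_numpy()
    keep = is_pre[:-1] & is_pre[1:]
    idx = np.flatnonzero(keep)
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    ax, ay = x[idx], y[idx]
    bx, by = x[idx + 1], y[idx + 1]
    out = pd.DataFrame(
        {
            "bird_id": track.bird_id,
            "t_start": df["timestamp"].to_numpy()[idx],
            "t_end": df["timestamp"].to_numpy()[idx + 1],
            "day_before_laying": df["days_before_laying"].to_numpy()[idx].astype(int),
        }
    )
    for lab in labels:
        region = buffers.regions[lab]
        if isinstance(region, CircleRegion):
            flags = _circle_flags(ax, ay, bx, by, region, semantics)
        else:
            geoms = np.array(
                [
                    Point(ax[i], ay[i])
                    if ax[i] == bx[i] and ay[i] == by[i]
                    else LineString([(ax[i], ay[i]), (bx[i], by[i])])
                    for i in range(len(ax))
                ],
                dtype=object,
            )
            target = (
                region.polygon
                if semantics == "closed_region"
                else region.polygon.boundary
            )
            flags = shapely.intersects(geoms, target)
        out[lab] = flags.astype(int)
    return out


def intersection_frequencies(
    records: pd.DataFrame, max_day: int = 45
) -> pd.DataFrame:
    """Per-day relative frequency of intersection for every region.

    One row per (day_before_laying, region): proportion of that day's
    segments flagged 1, with the segment count; days without segments are
    emitted with NaN frequency.
    """
    if records.empty:
        raise ValidationError("no segment records")
    labels = [c for c in REGION_ORDER if c in records.columns]
    rows = []
    grouped = records.groupby("day_before_laying")
    for day in range(1, max_day + 1):
        if day in grouped.groups:
            g = grouped.get_group(day)
            for lab in labels:
                rows.append(
                    {
                        "day_before_laying": day,
                        "region": lab,
                        "n_segments": len(g),
                        "frequency": float(g[lab].mean()),
                    }
                )
        else:
            for lab in labels:
                rows.append(
                    {
                        "day_before_laying": day,
                        "region": lab,
                        "n_segments": 0,
                        "frequency": np.nan,
                    }
                )
    return pd.DataFrame(rows)
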