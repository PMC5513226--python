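"""Utilization distributions and isopleth home ranges.

Two estimators feed the pipeline:

* a dynamic Brownian bridge movement model (dBBMM) for prenesting ranges:
  the UD is the time-weighted integral, over every inter-fix segment, of the
  Brownian-bridge position density — a bivariate normal centred on the
  straight line between consecutive fixes with variance

      var(t) = sigma2_m * t * (T - t) / T + (1 - t/T)^2 * err^2 + (t/T)^2 * err^2

  where ``sigma2_m`` (m^2/s) is the Brownian motion variance and ``err`` the
  GPS location error. ``sigma2_m`` is estimated locally by leave-one-out
  maximum likelihood in a sliding window of fixes (default 31 fixes, margin
  11), so behavioural change points at window margins are reflected in the
  variance profile;

* a fixed bivariate Gaussian kernel for incubation ranges, with one shared
  isotropic bandwidth (normal-scale rule per axis, averaged, by default).

Isopleths (50/75/95/99%) are probability-mass contours: the smallest set of
highest-density cells holding the stated mass, traced to polygons by
marching squares. Areas are reported in hectares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from skimage import measure
import shapely
from shapely.geometry import MultiPolygon, Point, Polygon

from .tracks_io import Track, ValidationError, get_logger

SQRT_2PI = np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------


@dataclass
class UDGrid:
    """Gridded utilization distribution; ``mass[iy, ix]`` sums to one.

    ``origin`` is the lower-left corner of cell (0, 0); cell centres sit at
    ``origin + (i + 0.5) * cell_size``.
    """

    origin: tuple[float, float]
    cell_size: float
    mass: np.ndarray  # shape (ny, nx)
    motion_variance: np.ndarray | None = None  # per-segment sigma2_m, m^2/s

    @property
    def density(self) -> np.ndarray:
        return self.mass / (self.cell_size**2)

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.mass.shape[1]) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.mass.shape[0]) + 0.5) * self.cell_size

    def total_mass(self) -> float:
        return float(self.mass.sum())


def make_grid(
    points: np.ndarray,
    pad: float,
    cell_size: float | None = None,
    max_cells_per_axis: int = 400,
    min_cell_size: float = 5.0,
) -> tuple[tuple[float, float], float, int, int]:
    """Grid geometry covering ``points`` with a ``pad`` margin on every side.

    Default resolution: ``max(min_cell_size, extent / max_cells_per_axis)``
    on the longer axis — printed range areas span two orders of magnitude,
    so a fixed cell size would be wrong at one end or the other.
    """
    pts = np.asarray(points, dtype=float)
    x0, y0 = pts.min(axis=0) - pad
    x1, y1 = pts.max(axis=0) + pad
    extent = max(x1 - x0, y1 - y0)
    if cell_size is None:
        cell_size = max(min_cell_size, extent / max_cells_per_axis)
    nx = max(8, int(np.ceil((x1 - x0) / cell_size)))
    ny = max(8, int(np.ceil((y1 - y0) / cell_size)))
    return (float(x0), float(y0)), float(cell_size), nx, ny


def _deposit_gaussian(
    mass: np.ndarray,
    xc: np.ndarray,
    yc: np.ndarray,
    mu: np.ndarray,
    sd: float,
    weight: float,
    cell: float,
    trunc: float = 5.0,
) -> None:
    """Add ``weight`` times an isotropic Gaussian (sd) to the mass grid.

    Separable outer-product evaluation restricted to a +-trunc*sd window.
    """
    lo_x = np.searchsorted(xc, mu[0] - trunc * sd)
    hi_x = np.searchsorted(xc, mu[0] + trunc * sd)
    lo_y = np.searchsorted(yc, mu[1] - trunc * sd)
    hi_y = np.searchsorted(yc, mu[1] + trunc * sd)
    if lo_x >= hi_x or lo_y >= hi_y:
        return
    gx = np.exp(-0.5 * ((xc[lo_x:hi_x] - mu[0]) / sd) ** 2) / (sd * SQRT_2PI)
    gy = np.exp(-0.5 * ((yc[lo_y:hi_y] - mu[1]) / sd) ** 2) / (sd * SQRT_2PI)
    mass[lo_y:hi_y, lo_x:hi_x] += weight * cell * cell * np.outer(gy, gx)


# ---------------------------------------------------------------------------
# Dynamic Brownian bridge
# ---------------------------------------------------------------------------


def _loo_neg_loglik(
    log_s2: float, coords: np.ndarray, times: np.ndarray, err: float
) -> float:
    """Negative leave-one-out log likelihood of sigma2_m for one fix window.

    Odd-indexed fixes are predicted from their even-indexed neighbours via
    the Brownian bridge; even fixes act as anchors, keeping the terms
    conditionally independent.
    """
    s2 = np.exp(log_s2)
    idx = np.arange(1, len(coords) - 1, 2)
    t0, t1, t2 = times[idx - 1], times[idx], times[idx + 1]
    alpha = (t1 - t0) / (t2 - t0)
    mu = coords[idx - 1] + alpha[:, None] * (coords[idx + 1] - coords[idx - 1])
    var = (t2 - t0) * alpha * (1 - alpha) * s2 + ((1 - alpha) ** 2 + alpha**2) * err**2
    r2 = np.sum((coords[idx] - mu) ** 2, axis=1)
    # bivariate isotropic normal
    ll = np.sum(-np.log(2 * np.pi * var) - r2 / (2 * var))
    return -ll


def _window_sigma2(coords: np.ndarray, times: np.ndarray, err: float) -> float:
    res = minimize_scalar(
        _loo_neg_loglik,
        bounds=(-14.0, 10.0),
        args=(coords, times, err),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(np.exp(res.x))


def estimate_motion_variance(
    track: Track,
    location_error: float = 10.0,
    window: int = 31,
    margin: int = 11,
) -> np.ndarray:
    """Per-segment Brownian motion variance sigma2_m (m^2/s).

    Sliding windows of ``window`` fixes; each window's leave-one-out ML
    estimate is assigned to the segments in its core (window minus the two
    margins) and overlapping assignments are averaged. Tracks shorter than
    one window fall back to a single global estimate (logged).
    """
    log = get_logger("range_estimation", track.bird_id)
    coords, times = track.coords, track.times_s
    n = len(coords)
    if n < 3:
        raise ValidationError(f"track {track.bird_id}: need >= 3 fixes")
    if np.any(np.diff(times) <= 0):
        raise ValidationError(f"track {track.bird_id}: non-increasing timestamps")
    n_seg = n - 1
    if n < window:
        log.warning("only %d fixes (< window %d): global sigma2_m", n, window)
        s2 = _window_sigma2(coords, times, location_error)
        return np.full(n_seg, s2)

    acc = np.zeros(n_seg)
    cnt = np.zeros(n_seg)
    for s in range(0, n - window + 1):
        sl = slice(s, s + window)
        s2 = _window_sigma2(coords[sl], times[sl], location_error)
        core = slice(s + margin, s + window - margin)  # segment indices
        acc[core] += s2
        cnt[core] += 1
    out = np.divide(acc, cnt, out=np.full(n_seg, np.nan), where=cnt > 0)
    # margins at the track ends inherit the nearest estimated value
    valid = np.where(cnt > 0)[0]
    if len(valid) == 0:  # window too small for any core; single estimate
        return np.full(n_seg, _window_sigma2(coords, times, location_error))
    out[: valid[0]] = out[valid[0]]
    out[valid[-1] + 1 :] = out[valid[-1]]
    return out


def fit_brownian_bridge(
    track: Track,
    location_error: float = 10.0,
    cell_size: float | None = None,
    window: int = 31,
    margin: int = 11,
    motion_variance: float | np.ndarray | None = None,
    time_steps_per_segment: int = 10,
    max_cells_per_axis: int = 400,
) -> UDGrid:
    """Dynamic Brownian bridge UD for one track.

    ``motion_variance`` overrides estimation with a fixed (scalar or
    per-segment) sigma2_m, which the two-fix analytic reduction relies on.
    Segments are weighted by duration; mass is normalized to one.
    """
    coords, times = track.coords, track.times_s
    if len(coords) < 2:
        raise ValidationError(f"track {track.bird_id}: need >= 2 fixes")
    if np.any(np.diff(times) <= 0):
        raise ValidationError(f"track {track.bird_id}: non-increasing timestamps")
    n_seg = len(coords) - 1
    if motion_variance is None:
        s2 = estimate_motion_variance(track, location_error, window, margin)
    else:
        s2 = np.broadcast_to(np.atleast_1d(np.asarray(motion_variance, float)), (n_seg,)).copy()

    durations = np.diff(times)
    # pad by the largest mid-bridge spread so the UD support fits the grid
    max_sd = float(
        np.sqrt(np.max(durations * s2) / 4.0 + location_error**2)
    )
    pad = max(3.0 * max_sd, 6.0 * location_error)
    origin, cell, nx, ny = make_grid(
        coords, pad=pad, cell_size=cell_size, max_cells_per_axis=max_cells_per_axis
    )
    mass = np.zeros((ny, nx))
    xc = origin[0] + (np.arange(nx) + 0.5) * cell
    yc = origin[1] + (np.arange(ny) + 0.5) * cell

    total_T = float(durations.sum())
    # quadrature step chosen so consecutive bridge means are spaced well
    # below the narrowest bridge sd (>= err/sqrt(2)) or the cell size
    min_sd = location_error / np.sqrt(2.0)
    spacing = max(0.25 * min_sd, 0.35 * cell)
    for i in range(n_seg):
        T = durations[i]
        dz = coords[i + 1] - coords[i]
        seg_len = float(np.hypot(*dz))
        K = int(np.clip(np.ceil(seg_len / spacing), time_steps_per_segment, 1200))
        w_seg = T / total_T / K
        for k in range(K):
            a = (k + 0.5) / K
            mu = coords[i] + a * dz
            var = T * a * (1 - a) * s2[i] + ((1 - a) ** 2 + a**2) * location_error**2
            _deposit_gaussian(mass, xc, yc, mu, np.sqrt(var), w_seg, cell)

    total = mass.sum()
    if total <= 0:
        raise ValidationError(f"track {track.bird_id}: empty UD (grid too coarse?)")
    mass /= total
    return UDGrid(origin=origin, cell_size=cell, mass=mass, motion_variance=s2)


# ---------------------------------------------------------------------------
# Fixed kernel
# ---------------------------------------------------------------------------


def reference_bandwidth(points: np.ndarray) -> float:
    """Normal-scale bandwidth per axis, averaged to one isotropic h.

    h_j = sigma_j * n^(-1/6) (the d=2 normal reference rule).
    """
    pts = np.asarray(points, float)
    n = len(pts)
    sds = pts.std(axis=0, ddof=1)
    return float(np.mean(sds) * n ** (-1.0 / 6.0))


def fit_fixed_kernel(
    points: np.ndarray,
    bandwidth: float | None = None,
    cell_size: float | None = None,
    max_cells_per_axis: int = 400,
) -> UDGrid:
    """Fixed-bandwidth bivariate Gaussian kernel UD (mass normalized to 1)."""
    pts = np.asarray(points, float)
    if len(pts) == 1 and bandwidth is not None:
        pass
    elif len(pts) < 5:
        raise ValidationError(f"fixed kernel needs >= 5 points, got {len(pts)}")
    if bandwidth is None:
        bandwidth = reference_bandwidth(pts)
    if not np.isfinite(bandwidth) or bandwidth <= 0:
        raise ValidationError(
            "degenerate point set (zero spread): pass an explicit minimum "
            "bandwidth override"
        )
    origin, cell, nx, ny = make_grid(
        pts,
        pad=6.5 * bandwidth,
        cell_size=cell_size if cell_size is not None else min(
            bandwidth / 4.0, max(5.0, 8.0 * bandwidth / max_cells_per_axis)
        ),
        max_cells_per_axis=max_cells_per_axis,
        min_cell_size=0.0,
    )
    mass = np.zeros((ny, nx))
    xc = origin[0] + (np.arange(nx) + 0.5) * cell
    yc = origin[1] + (np.arange(ny) + 0.5) * cell
    w = 1.0 / len(pts)
    for p in pts:
        _deposit_gaussian(mass, xc, yc, p, bandwidth, w, cell, trunc=6.0)
    total = mass.sum()
    if total <= 0:
        raise ValidationError("empty kernel UD")
    mass /= total
    return UDGrid(origin=origin, cell_size=cell, mass=mass)


# ---------------------------------------------------------------------------
# Isopleths
# ---------------------------------------------------------------------------


@dataclass
class IsoplethPolygon:
    level: float
    geometry: MultiPolygon
    area_ha: float
    threshold_density: float
    contained_mass: float

    @property
    def rings(self) -> list[Polygon]:
        return list(self.geometry.geoms)


def _rings_to_multipolygon(rings: list[np.ndarray]) -> MultiPolygon:
    """Assemble closed rings into shells with holes by containment parity."""
    polys = [Polygon(r) for r in rings if len(r) >= 4]
    polys = [p for p in polys if p.area > 0]
    if not polys:
        return MultiPolygon([])
    order = np.argsort([-p.area for p in polys])
    polys = [polys[i] for i in order]
    depth = []
    for i, p in enumerate(polys):
        rep = p.representative_point()
        depth.append(sum(1 for j in range(i) if polys[j].contains(rep)))
    shells = [
        (i, p) for i, (p, d) in enumerate(zip(polys, depth)) if d % 2 == 0
    ]
    out: list[Polygon] = []
    for i, shell in shells:
        holes = [
            polys[j].exterior.coords
            for j in range(len(polys))
            if depth[j] == depth[i] + 1 and j != i and shell.contains(
                polys[j].representative_point()
            )
        ]
        out.append(Polygon(shell.exterior.coords, holes))
    return MultiPolygon(out)


def extract_isopleth(ud: UDGrid, level: float) -> IsoplethPolygon:
    """Probability-mass contour polygon at the given level.

    Cells are ranked by density; the smallest prefix holding >= ``level`` of
    the mass defines the isopleth set, whose boundary is traced by marching
    squares. Ties (flat densities, e.g. a uniform UD) are resolved by the
    stable cell ordering so the contained mass stays within one cell of the
    level.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"isopleth level {level} outside (0,1)")
    dens = ud.density
    flat = dens.ravel()
    order = np.argsort(-flat, kind="stable")
    cum = np.cumsum(ud.mass.ravel()[order])
    m = int(np.searchsorted(cum, level)) + 1
    m = min(m, len(flat))
    q = float(flat[order[m - 1]])
    contained = float(cum[m - 1])

    n_ge = int(np.count_nonzero(flat >= q)) if q > 0 else len(flat)
    use_mask = q <= 0 or n_ge > m + max(2, int(0.02 * m))

    cell = ud.cell_size
    if use_mask:
        sel = np.zeros(flat.shape, dtype=float)
        sel[order[:m]] = 1.0
        field2d = sel.reshape(dens.shape)
        contour_level = 0.5
    else:
        field2d = dens
        contour_level = q * (1 - 1e-9)

    padded = np.pad(field2d, 1, constant_values=0.0)
    contours = measure.find_contours(padded, contour_level)
    rings = []
    for c in contours:
        # padded index -> world: row/col i maps to centre of cell i-1
        xy = np.empty_like(c)
        xy[:, 0] = ud.origin[0] + (c[:, 1] - 1 + 0.5) * cell
        xy[:, 1] = ud.origin[1] + (c[:, 0] - 1 + 0.5) * cell
        rings.append(xy)
    geom = _rings_to_multipolygon(rings)
    area_ha = geom.area / 1e4
    return IsoplethPolygon(
        level=level,
        geometry=geom,
        area_ha=float(area_ha),
        threshold_density=q,
        contained_mass=contained,
    )


def contains_point(iso: IsoplethPolygon, p: tuple[float, float]) -> bool:
    """Even-odd containment; boundary points count as inside."""
    return bool(iso.geometry.covers(Point(p)))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def save_ud(ud: UDGrid, path) -> None:
    header = (
        f"origin_x {ud.origin[0]:.6f}\norigin_y {ud.origin[1]:.6f}\n"
        f"cell_size {ud.cell_size:.6f}\nncols {ud.mass.shape[1]}\n"
        f"nrows {ud.mass.shape[0]}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, ud.mass, fmt="%.9e")


def load_ud(path) -> UDGrid:
    with open(path) as fh:
        hdr = {}
        for _ in range(5):
            k, v = fh.readline().split()
            hdr[k] = float(v)
        mass = np.loadtxt(fh)
    mass = mass.reshape(int(hdr["nrows"]), int(hdr["ncols"]))
    return UDGrid(
        origin=(hdr["origin_x"], hdr["origin_y"]),
        cell_size=hdr["cell_size"],
        mass=mass,
    )


def isopleth_to_geojson(iso: IsoplethPolygon) -> dict:
    return {
        "type": "Feature",
        "properties": {"level": iso.level, "area_ha": iso.area_ha},
        "geometry": shapely.geometry.mapping(iso.geometry),
    }
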