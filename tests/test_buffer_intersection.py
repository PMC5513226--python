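import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from shapely.geometry import MultiPolygon, Point

from nestmove.buffer_intersection import (
    CircleRegion,
    PolygonRegion,
    build_buffers,
    classify_segments,
    equivalent_radius,
    intersection_frequencies,
    segment_intersects,
)
from nestmove.phenology import delineate_phases
from nestmove.range_estimation import fit_fixed_kernel
from nestmove.tracks_io import AnalysisConfig, NestAttempt, ValidationError

from conftest import make_scheduled_track

D0 = dt.date(2023, 3, 1)


class TestEquivalentRadius:
    def test_unit_circle(self):
        assert equivalent_radius(math.pi) == pytest.approx(1.0)

    def test_typical_incubation_extent(self):
        # 1.46 ha -> a circle of the same area has radius ~68.17 m
        assert equivalent_radius(1.46e4) == pytest.approx(68.17, abs=0.005)

    @pytest.mark.parametrize("bad", [0.0, -3.0])
    def test_nonpositive_area_rejected(self, bad):
        with pytest.raises(ValidationError):
            equivalent_radius(bad)


class TestBuildBuffers:
    def test_population_mean_radius_by_subspecies(self):
        cfg = AnalysisConfig()
        east = build_buffers((0, 0), None, "eastern", cfg)
        rio = build_buffers((0, 0), None, "rio_grande", cfg)
        assert east.regions["mean_incubation_circle"].radius == 55.24
        assert rio.regions["mean_incubation_circle"].radius == 70.82

    def test_fixed_circles_independent_of_ud(self):
        buf = build_buffers((10, 20), None, "eastern", AnalysisConfig())
        assert buf.regions["fixed_100m"].radius == 100.0
        assert buf.regions["fixed_500m"].radius == 500.0
        assert buf.regions["fixed_100m"].center == (10, 20)

    def test_missing_ud_builds_three_regions(self):
        buf = build_buffers((0, 0), None, "eastern", AnalysisConfig())
        assert set(buf.regions) == {
            "mean_incubation_circle",
            "fixed_100m",
            "fixed_500m",
        }

    def test_kernel_regions_from_incubation_ud(self, rng):
        pts = rng.normal(0.0, 20.0, size=(200, 2))
        ud = fit_fixed_kernel(pts)
        buf = build_buffers((0, 0), ud, "eastern", AnalysisConfig())
        assert len(buf.regions) == 5
        r95 = buf.regions["kernel95_equiv_circle"].radius
        assert r95 == pytest.approx(
            equivalent_radius(
                __import__("nestmove.range_estimation", fromlist=["extract_isopleth"])
                .extract_isopleth(ud, 0.95)
                .area_ha
                * 1e4
            )
        )
        assert isinstance(buf.regions["kernel75_polygon"], PolygonRegion)


class TestSegmentIntersects:
    def test_close_approach_inside_radius(self):
        c = CircleRegion((100.0, 50.0), 60.0)
        assert segment_intersects((0, 0), (200, 0), c)  # approach 50 m

    def test_close_approach_outside_radius(self):
        c = CircleRegion((100.0, 80.0), 60.0)
        assert not segment_intersects((0, 0), (200, 0), c)  # approach 80 m

    def test_containment_counts_by_default_not_for_crossing(self):
        c = CircleRegion((0.0, 0.0), 500.0)
        seg = ((-50, 0), (50, 0))
        assert segment_intersects(*seg, c, semantics="closed_region")
        assert not segment_intersects(*seg, c, semantics="boundary_crossing")
        # a segment that pierces the boundary counts under both semantics
        pierce = ((0, 0), (1000, 0))
        assert segment_intersects(*pierce, c, semantics="closed_region")
        assert segment_intersects(*pierce, c, semantics="boundary_crossing")

    def test_zero_length_segment_by_point_containment(self):
        c = CircleRegion((0.0, 0.0), 10.0)
        assert segment_intersects((5, 0), (5, 0), c)
        assert not segment_intersects((50, 0), (50, 0), c)

    def test_polygon_region(self):
        poly = MultiPolygon([Point(0, 0).buffer(100.0)])
        r = PolygonRegion(poly)
        assert segment_intersects((-200, 0), (200, 0), r)
        assert not segment_intersects((-200, 150), (200, 150), r)

    @given(
        ax=st.floats(-500, 500), ay=st.floats(-500, 500),
        bx=st.floats(-500, 500), by=st.floats(-500, 500),
        cx=st.floats(-500, 500), cy=st.floats(-500, 500),
        r1=st.floats(10, 100), extra=st.floats(1, 200),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_concentric_monotonicity(self, ax, ay, bx, by, cx, cy, r1, extra):
        small = CircleRegion((cx, cy), r1)
        big = CircleRegion((cx, cy), r1 + extra)
        if segment_intersects((ax, ay), (bx, by), small):
            assert segment_intersects((ax, ay), (bx, by), big)

    @given(
        ax=st.floats(-300, 300), ay=st.floats(-300, 300),
        bx=st.floats(-300, 300), by=st.floats(-300, 300),
        r=st.floats(5, 150), theta=st.floats(0, 2 * math.pi),
        tx=st.floats(-1000, 1000), ty=st.floats(-1000, 1000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rigid_motion_invariance(self, ax, ay, bx, by, r, theta, tx, ty):
        # classification is only rotation-stable away from the knife edge
        # where the closest approach equals the radius to within rounding
        seg = np.array([[ax, ay], [bx, by]])
        ab = seg[1] - seg[0]
        t = 0.0 if ab @ ab == 0 else float(np.clip(-(seg[0] @ ab) / (ab @ ab), 0, 1))
        dmin = float(np.hypot(*(seg[0] + t * ab)))
        assume(abs(dmin - r) > 1e-6 * (1.0 + dmin))
        circle = CircleRegion((0.0, 0.0), r)
        base = segment_intersects((ax, ay), (bx, by), circle)
        ct, stn = math.cos(theta), math.sin(theta)

        def move(x, y):
            return (ct * x - stn * y + tx, stn * x + ct * y + ty)

        moved = CircleRegion(move(0.0, 0.0), r)
        assert segment_intersects(move(ax, ay), move(bx, by), moved) == base


def dense_oracle(a, b, region, n=10_000):
    """Membership of n points sampled densely along the closed segment."""
    t = np.linspace(0.0, 1.0, n)
    xs = a[0] + t * (b[0] - a[0])
    ys = a[1] + t * (b[1] - a[1])
    if isinstance(region, CircleRegion):
        inside = np.hypot(xs - region.center[0], ys - region.center[1]) <= region.radius
        return bool(inside.any())
    import shapely

    pts = shapely.points(xs, ys)
    return bool(shapely.intersects(pts, region.polygon).any())


def random_instances(rng, n):
    for _ in range(n):
        a = rng.uniform(-400, 400, 2)
        b = rng.uniform(-400, 400, 2)
        if rng.random() < 0.7:
            region = CircleRegion(tuple(rng.uniform(-300, 300, 2)), rng.uniform(20, 250))
        else:
            center = rng.uniform(-300, 300, 2)
            region = PolygonRegion(
                MultiPolygon([Point(*center).buffer(rng.uniform(30, 200), quad_segs=32)])
            )
        yield tuple(a), tuple(b), region


def test_classifier_agrees_with_dense_sampling_oracle(rng):
    for a, b, region in random_instances(rng, 300):
        assert segment_intersects(a, b, region) == dense_oracle(a, b, region)


class TestClassifySegments:
    @pytest.fixture()
    def phased(self):
        positions = {}
        for i in range(43, 45):  # two prenesting days
            positions[D0 + dt.timedelta(days=i)] = (
                {h: (1000.0 - 50 * h, 0.0) for h in (*range(6, 21), 0)}
            )
        positions[D0 + dt.timedelta(days=45)] = (2000.0, 0.0)  # laying day
        tr = make_scheduled_track("b", positions)
        nest = NestAttempt(
            "b", 0.0, 0.0,
            laying_onset=D0 + dt.timedelta(days=45),
            incubation_onset=D0 + dt.timedelta(days=47),
        )
        labels = delineate_phases(tr, nest, AnalysisConfig())
        buffers = build_buffers(nest.nest, None, "rio_grande", AnalysisConfig())
        return tr, labels, buffers

    def test_segments_restricted_to_prenesting(self, phased):
        tr, labels, buffers = phased
        segs = classify_segments(tr, labels, buffers)
        n_pre_fixes = int((labels.phase == "prenesting").sum())
        assert len(segs) == n_pre_fixes - 1  # consecutive pairs only
        assert set(segs["day_before_laying"]) == {1, 2}

    def test_day_attribution_by_starting_fix(self, phased):
        tr, labels, buffers = phased
        segs = classify_segments(tr, labels, buffers)
        # the midnight-spanning segment starts on the earlier day (2 before)
        crossing = segs[segs["t_start"].dt.hour == 20]
        assert (crossing["day_before_laying"] == 2).any()

    def test_flags_defined_for_all_regions(self, phased):
        tr, labels, buffers = phased
        segs = classify_segments(tr, labels, buffers)
        for lab in buffers.labels:
            assert segs[lab].isin([0, 1]).all()

    def test_region_monotonicity_on_track(self, phased):
        tr, labels, buffers = phased
        segs = classify_segments(tr, labels, buffers)
        assert (segs["fixed_100m"] <= segs["fixed_500m"]).all()


class TestIntersectionFrequencies:
    def make_records(self, flags_by_day):
        import pandas as pd

        rows = []
        for day, flags in flags_by_day.items():
            for f in flags:
                rows.append(
                    {
                        "bird_id": "b",
                        "t_start": None,
                        "t_end": None,
                        "day_before_laying": day,
                        "fixed_100m": f,
                    }
                )
        return pd.DataFrame(rows)

    def test_all_zero_flags(self):
        rec = self.make_records({d: [0, 0] for d in range(1, 46)})
        out = intersection_frequencies(rec)
        assert (out["frequency"] == 0).all()

    def test_alternating_single_segments(self):
        rec = self.make_records({d: [d % 2] for d in range(1, 46)})
        out = intersection_frequencies(rec)
        freq = out.set_index("day_before_laying")["frequency"]
        assert freq.loc[1] == 1.0 and freq.loc[2] == 0.0

    def test_missing_day_emitted_as_nan(self):
        rec = self.make_records({1: [1], 3: [0]})
        out = intersection_frequencies(rec, max_day=3)
        day2 = out[out["day_before_laying"] == 2]
        assert day2["n_segments"].item() == 0
        assert np.isnan(day2["frequency"].item())

    def test_empty_records_error(self):
        import pandas as pd

        with pytest.raises(ValidationError):
            intersection_frequencies(pd.DataFrame())
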