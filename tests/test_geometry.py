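"""Aortic segment construction against hand-derived coordinate oracles."""

import numpy as np
import pytest
from shapely.geometry import Point

from aacscore import (build_aas, build_boundaries, crop_aas, extend_boundary,
                      generate_phantom, segments_from_landmarks)
from aacscore.geometry import GeometryError, polygon_mask
from aacscore.phantom import PhantomConfig, _quad_point

from conftest import make_axis_aligned_vertebrae, transform_vertebrae


@pytest.fixture(scope="module")
def column():
    # L1 upper corners at y=20, x in {10, 52}; gap 10 -> midlines at y=85, ...
    return make_axis_aligned_vertebrae(x_left=10.0, x_right=52.0, y_top=20.0,
                                       length=60.0, gap=10.0)


class TestBoundaries:
    def test_top_boundary_joins_l1_upper_corners(self, column):
        b0 = build_boundaries(column, "left")[0]
        assert (b0.posterior_point.x, b0.posterior_point.y) == (52.0, 20.0)
        assert (b0.anterior_point.x, b0.anterior_point.y) == (10.0, 20.0)
        assert b0.length == pytest.approx(42.0)

    def test_intervertebral_midpoint_arithmetic(self, column):
        # L1 lower corners y=80, L2 upper corners y=90 -> boundary at y=85
        b1 = build_boundaries(column, "left")[1]
        assert b1.anterior_point.y == pytest.approx(85.0)
        assert b1.posterior_point.y == pytest.approx(85.0)
        assert b1.anterior_point.x == pytest.approx(10.0)
        assert b1.posterior_point.x == pytest.approx(52.0)

    def test_anterior_side_right_flips_orientation(self, column):
        b0 = build_boundaries(column, "right")[0]
        assert b0.anterior_point.x == 52.0
        assert b0.posterior_point.x == 10.0

    def test_rotation_equivariance(self, column):
        """Boundaries of a rigidly rotated column are the rotated
        boundaries of the original (within 1e-9 px)."""
        rotated = transform_vertebrae(column, rotation_deg=10.0,
                                      center=(31.0, 195.0))
        base = build_boundaries(column, "left")
        rot = build_boundaries(rotated, "left")
        th = np.deg2rad(10.0)
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.array([31.0, 195.0])
        for b, br in zip(base, rot):
            for attr in ("posterior_point", "anterior_point"):
                expect = r @ (getattr(b, attr).as_array() - c) + c
                got = getattr(br, attr).as_array()
                assert np.abs(got - expect).max() < 1e-9

    def test_vertical_boundary_rejected(self, column):
        """If L1's two upper corners share x, the top boundary is vertical
        and the anterior side cannot hold."""
        from aacscore.landmarks import Landmark, Vertebra, VertebraSet
        vs = list(column)
        l1 = vs[0]
        corners = dict(l1.corners)
        corners["upper_left"] = Landmark(30.0, 10.0)
        corners["upper_right"] = Landmark(30.0, 18.0)
        broken = VertebraSet([Vertebra("L1", corners)] + vs[1:])
        with pytest.raises(GeometryError, match="anterior side"):
            build_boundaries(broken, "left")


class TestExtension:
    def test_tip_doubles_past_anterior_end(self, column):
        b0 = build_boundaries(column, "left")[0]
        ext = extend_boundary(b0)
        assert (ext.tip.x, ext.tip.y) == (-32.0, 20.0)

    def test_extension_length_identity(self, column):
        for b in build_boundaries(column, "left"):
            ext = extend_boundary(b)
            d = np.linalg.norm(ext.tip.as_array()
                               - b.anterior_point.as_array())
            assert d == pytest.approx(b.length, abs=1e-9)

    def test_tip_collinearity(self, column):
        for b in build_boundaries(column, "left"):
            a = b.anterior_point.as_array()
            p = b.posterior_point.as_array()
            t = extend_boundary(b).tip.as_array()
            u, v = a - p, t - p
            assert abs(u[0] * v[1] - u[1] * v[0]) < 1e-9


class TestSegments:
    def test_axis_aligned_segments_are_hand_derived_rectangles(self, column):
        """Boundaries sit at y = 20 (L1 top) and the midlines 85/155/225/295,
        so segment heights are 65, 70, 70, 70 and width = vertebra width."""
        segs = segments_from_landmarks(column, "left")
        assert [s.level for s in segs] == ["L1", "L2", "L3", "L4"]
        for s, height in zip(segs, (65.0, 70.0, 70.0, 70.0)):
            xs = sorted({round(p.x, 9) for p in s.polygon})
            assert xs == [-32.0, 10.0]  # width = vertebra width 42
            assert s.area == pytest.approx(42.0 * height, abs=1e-9)

    def test_tiling_without_overlap(self, column):
        segs = segments_from_landmarks(column, "left")
        polys = [s.shapely() for s in segs]
        total = sum(p.area for p in polys)
        for i in range(4):
            for j in range(i + 1, 4):
                inter = polys[i].intersection(polys[j])
                assert inter.area < 1e-9
                if j == i + 1:  # consecutive segments share one full edge:
                    # the extended boundary from anterior point to tip (42 px)
                    assert inter.length == pytest.approx(42.0)
        union = polys[0]
        for p in polys[1:]:
            union = union.union(p)
        assert union.area == pytest.approx(total)

    def test_rigid_motion_equivariance_of_polygons(self, column):
        moved = transform_vertebrae(column, rotation_deg=7.0, dx=5.0,
                                    dy=-3.0, center=(31.0, 195.0))
        th = np.deg2rad(7.0)
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.array([31.0, 195.0])
        for s, sm in zip(segments_from_landmarks(column, "left"),
                         segments_from_landmarks(moved, "left")):
            for p, pm in zip(s.polygon, sm.polygon):
                expect = r @ (p.as_array() - c) + c + (5.0, -3.0)
                assert np.abs(pm.as_array() - expect).max() < 1e-6

    def test_phantom_plaques_inside_their_segment(self, default_config):
        ph = generate_phantom(default_config, "random")
        segs = {s.level: s for s in ph.segments()}
        for p in ph.plaques:
            seg = segs[p.segment_level]
            s = 0.65 if p.wall == "anterior" else 0.35
            mid = _quad_point(seg, p.start_fraction
                              + p.coverage_fraction / 2, s)
            assert segs[p.segment_level].shapely().buffer(1e-9).contains(
                Point(mid))
            for other_level, other in segs.items():
                if other_level != p.segment_level:
                    assert not other.shapely().buffer(-1e-6).contains(
                        Point(mid))


class TestCrop:
    def test_rectangle_crop_is_pure_resize(self, column):
        """A rectangle polygon equal to its bounding box resamples the
        region without masking: a constant region stays constant."""
        img = np.full((300, 100), 7.0)
        s = segments_from_landmarks(column, "right")[0]
        out = crop_aas(img, s, 70, 42)
        interior = out[3:-3, 3:-3]  # rasterization rim excluded
        assert np.allclose(interior, 7.0)

    def test_off_frame_area_reads_zero(self, column):
        img = np.full((300, 100), 50.0)
        s = segments_from_landmarks(column, "left")[0]  # spans x<0
        out = crop_aas(img, s, 70, 84)
        assert out[:, :5].max() == 0.0   # off-frame left portion
        assert out[:, -5:].max() > 0.0

    def test_polygon_outside_frame_errors(self, column):
        s = segments_from_landmarks(column, "left")[0]
        with pytest.raises(GeometryError, match="outside"):
            crop_aas(np.zeros((10, 5)), s, 8, 8)

    def test_crop_isolates_level_plaques(self, default_config):
        """The L3 crop contains L3 plaque brightness; the L2/L4 crops show
        none of it (mask bookkeeping against generator metadata)."""
        ph = generate_phantom(
            default_config, {("L3", "anterior"): 3})
        base = generate_phantom(default_config, {})
        segs = {s.level: s for s in ph.segments()}
        for level, expect_bright in (("L2", False), ("L3", True),
                                     ("L4", False)):
            diff = (crop_aas(ph.image, segs[level], 48, 32)
                    - crop_aas(base.image, segs[level], 48, 32))
            if expect_bright:
                assert diff.max() > 50
            else:
                assert np.percentile(np.abs(diff), 99) < 30

    def test_invalid_output_dims(self, column):
        s = segments_from_landmarks(column, "left")[0]
        with pytest.raises(ValueError):
            crop_aas(np.zeros((300, 100)), s, 0, 10)
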