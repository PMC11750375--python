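"""Geometry construction, validation, sampling and area accounting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point

import bifstokes as B
from bifstokes.geometry import (GeometryError, OPENING_TAGS, WALL,
                                PARTICLE as PARTICLE_TAG)


class TestValidation:
    @pytest.mark.parametrize("spec,ok,needle", [
        (B.BifurcationSpec(1, 1, math.pi / 8, math.pi / 8), False, "overlap"),
        (B.BifurcationSpec(1, 1, math.pi / 4, math.pi / 4), True, None),
        (B.BifurcationSpec(0.5, 1, math.pi / 4, math.pi / 4), True, None),
        (B.BifurcationSpec(1, 1, math.pi / 2, 0.0), True, None),
        (B.BifurcationSpec(1, 1, math.pi / 2, math.pi / 2), True, None),
        (B.BifurcationSpec(0.5, 0.5, 0.0, 0.0), False, None),
        (B.BifurcationSpec(0.6, 0.8, 0.3, 0.3), False, "pinch"),
        (B.BifurcationSpec(-0.1, 1, 0.5, 0.5), False, "width"),
    ])
    def test_admissibility(self, spec, ok, needle):
        report = B.validate_spec(spec)
        assert report.ok == ok
        if needle:
            assert any(needle in v for v in report.violations)

    def test_build_raises_with_named_predicate(self):
        with pytest.raises(GeometryError, match="overlap"):
            B.build_bifurcation(B.BifurcationSpec(1, 1, 0.3, 0.3))

    def test_particle_clearance(self):
        bad = B.BifurcationSpec(1, 1, math.pi / 4, math.pi / 4,
                                particle=(-1.0, 0.45, 0.1))
        assert not B.validate_spec(bad).ok
        good = B.BifurcationSpec(1, 1, math.pi / 4, math.pi / 4,
                                 particle=(0.0, 0.0, 0.2))
        assert B.validate_spec(good).ok


class TestConstruction:
    def test_reference_openings_and_corners(self, ref_domain):
        inlet = ref_domain.openings[0]
        assert inlet.lo == pytest.approx(complex(-2, -0.5))
        assert inlet.hi == pytest.approx(complex(-2, 0.5))
        assert len(ref_domain.corners) == 3
        assert all(c.reentrant for c in ref_domain.corners)
        # every corner lies on both of its wall lines: check it lies on the
        # boundary polygon
        for c in ref_domain.corners:
            assert ref_domain.polygon.exterior.distance(
                Point(c.point.real, c.point.imag)) < 1e-12
        # child openings sit at centreline distance L with the right widths
        for op, w in zip(ref_domain.openings, (1.0, 0.9, 0.8)):
            assert op.width == pytest.approx(w)
            if op.index:
                assert abs(op.center) == pytest.approx(2.0)

    def test_symmetric_domain_mirrors(self, sym_domain):
        cs = [c.point for c in sym_domain.corners]
        top = [c for c in cs if c.imag > 0.1]
        bot = [c for c in cs if c.imag < -0.1]
        assert len(top) == len(bot) == 1
        assert top[0] == pytest.approx(bot[0].conjugate(), abs=1e-12)
        a0, a1, a2 = B.region_areas(sym_domain)
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_collinear_child_gives_flat_corner(self):
        dom = B.build_bifurcation(B.BifurcationSpec(1, 1, math.pi / 2, 0.0))
        flat = [c for c in dom.corners if not c.reentrant]
        assert len(flat) == 1
        assert flat[0].point == pytest.approx(complex(0, -0.5))
        assert flat[0].interior_angle == pytest.approx(math.pi)

    def test_swapped_spec_reflects_domain(self):
        spec = B.BifurcationSpec(0.7, 0.95, 0.6, 1.1)
        a = B.region_areas(B.build_bifurcation(spec))
        b = B.region_areas(B.build_bifurcation(spec.swapped()))
        assert a[0] == pytest.approx(b[0], rel=1e-9)
        assert a[1] == pytest.approx(b[2], rel=1e-9)
        assert a[2] == pytest.approx(b[1], rel=1e-9)


class TestAreas:
    def test_additivity_and_positivity(self, ref_domain):
        areas = B.region_areas(ref_domain)
        assert all(a > 0 for a in areas)
        assert sum(areas) == pytest.approx(ref_domain.fluid_area, rel=1e-9)

    def test_particle_area_deficit(self):
        base = B.BifurcationSpec(1, 1, math.pi / 4, math.pi / 4)
        with_hole = B.BifurcationSpec(1, 1, math.pi / 4, math.pi / 4,
                                      particle=(0.0, 0.0, 0.2))
        a0 = sum(B.region_areas(B.build_bifurcation(base)))
        a1 = sum(B.region_areas(B.build_bifurcation(with_hole)))
        assert a0 - a1 == pytest.approx(math.pi * 0.2**2, rel=1e-4)

    def test_monte_carlo_cross_check(self, sym_domain):
        import shapely
        rng = np.random.default_rng(42)
        n = 10**6
        poly = sym_domain.region_polygons[1]  # child-1 region
        minx, miny, maxx, maxy = poly.bounds
        xs = rng.uniform(minx, maxx, n)
        ys = rng.uniform(miny, maxy, n)
        inside = shapely.contains_xy(poly, xs, ys)
        p = inside.mean()
        est = p * (maxx - minx) * (maxy - miny)
        se = (maxx - minx) * (maxy - miny) * math.sqrt(p * (1 - p) / n)
        assert abs(est - poly.area) < 3 * se

    def test_curved_walls_change_area(self):
        s = B.BifurcationSpec(0.9, 0.8, math.pi / 4, math.pi / 3)
        c = B.BifurcationSpec(0.9, 0.8, math.pi / 4, math.pi / 3,
                              wall_kind="bezier")
        assert (B.build_bifurcation(c).fluid_area
                > B.build_bifurcation(s).fluid_area)


class TestSampling:
    def test_samples_on_boundary_with_valid_frames(self, ref_domain):
        s = B.sample_boundary(ref_domain)
        assert (s.weights > 0).all()
        assert np.allclose(np.abs(s.tangents), 1.0, atol=1e-12)
        assert np.allclose(np.abs(s.normals), 1.0, atol=1e-12)
        bdry = ref_domain.polygon.exterior
        dmax = max(bdry.distance(Point(z.real, z.imag))
                   for z in s.points[::17])
        assert dmax < 1e-12
        for tag in OPENING_TAGS:
            assert (s.bc_tag == tag).sum() > 0

    def test_pressures_land_on_opening_samples(self, ref_domain):
        s = B.sample_boundary(ref_domain, pressures=(0.0, -1.0, -2.0))
        assert np.all(np.isnan(s.bc_value[s.bc_tag == WALL]))
        assert np.all(s.bc_value[s.bc_tag == OPENING_TAGS[2]] == -2.0)

    def test_particle_circle_sampling(self):
        spec = B.BifurcationSpec(1, 1, math.pi / 4, math.pi / 4,
                                 particle=(0.0, 0.0, 0.2))
        dom = B.build_bifurcation(spec)
        s = B.sample_boundary(dom, particle_points=100)
        m = s.bc_tag == PARTICLE_TAG
        assert m.sum() == 100
        assert np.allclose(np.abs(s.points[m]), 0.2, atol=1e-12)
        # uniform spacing on the circle
        w = s.weights[m]
        assert np.allclose(w, 2 * math.pi * 0.2 / 100)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(d1=st.floats(0.5, 1.0), d2=st.floats(0.5, 1.0),
       alpha=st.floats(0.0, math.pi / 2), beta=st.floats(0.0, math.pi / 2))
def test_valid_specs_build_consistent_domains(d1, d2, alpha, beta):
    """Any spec passing validation yields a simple polygon whose region
    areas are positive and additive, and mirrors under the child swap."""
    spec = B.BifurcationSpec(d1, d2, alpha, beta)
    report = B.validate_spec(spec)
    if not report.ok:
        return
    dom = B.build_bifurcation(spec)
    assert dom.polygon.is_valid and dom.polygon.is_simple
    areas = B.region_areas(dom)
    assert all(a > 0 for a in areas)
    swapped = spec.swapped()
    if B.validate_spec(swapped).ok:
        sa = B.region_areas(B.build_bifurcation(swapped))
        assert sa[1] == pytest.approx(areas[2], rel=1e-8, abs=1e-12)
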