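"""Solver correctness: analytic oracles, symmetries, residual behaviour."""

import math

import numpy as np
import pytest

import bifstokes as B

from conftest import LIGHT, REF, SYM


def plane_poiseuille_goursat(z):
    """Closed-form Goursat pair for U = 1 - 4 Y^2, V = 0 on a width-1 slab:
    f = -z^2, g' = 1 + z^2 (g = z + z^3/3)."""
    f = -z**2
    f1 = -2 * z
    g = z + z**3 / 3
    g1 = 1 + z**2
    return f, f1, g, g1


class TestVelocityRelation:
    def test_plane_poiseuille_closed_form(self):
        """The Goursat velocity/pressure relations reproduce the known
        parabolic channel flow, pinning the conjugation convention."""
        rng = np.random.default_rng(3)
        z = rng.uniform(-2, 2, 50) + 1j * rng.uniform(-0.5, 0.5, 50)
        f, f1, g, g1 = plane_poiseuille_goursat(z)
        W = -np.conj(f) + np.conj(z) * f1 + g1
        U, V = W.real, -W.imag
        PO = 4 * f1
        assert U == pytest.approx(1 - 4 * z.imag**2, abs=1e-12)
        assert V == pytest.approx(np.zeros(50), abs=1e-12)
        assert PO.real == pytest.approx(-8 * z.real, abs=1e-12)
        assert -PO.imag == pytest.approx(8 * z.imag, abs=1e-12)
        psi = np.imag(np.conj(z) * f + g)
        assert psi == pytest.approx(z.imag - (4 / 3) * z.imag**3, abs=1e-12)


@pytest.fixture(scope="module")
def rect_solution():
    dom = B.rectangle_channel(1.0, 4.0)
    opts = B.SolverOptions(poly_degree=10, wall_uniform=60,
                           opening_points=40)
    return dom, B.solve_stokes(dom, (0.0, -1.0), opts)


class TestRectangleChannel:

    def test_conductance_matches_poiseuille_law(self, rect_solution):
        dom, sol = rect_solution
        op = dom.openings[0]
        psi = sol.fields_raw(np.array([op.lo, op.hi]))[4]
        flux = psi[1] - psi[0]
        assert flux == pytest.approx(1.0 / 48.0, abs=1e-8)

    def test_machine_level_residual(self, rect_solution):
        _, sol = rect_solution
        assert sol.residual_report["overall"] < 1e-12

    def test_normal_stress_mode_agrees(self):
        """For developed channel flow the normal stress equals -P, so the
        normal-stress opening rows give the same conductance."""
        dom = B.rectangle_channel(1.0, 4.0)
        opts = B.SolverOptions(poly_degree=10, wall_uniform=60,
                               opening_points=40, bc_mode="normal_stress")
        sol = B.solve_stokes(dom, (0.0, -1.0), opts)
        op = dom.openings[0]
        psi = sol.fields_raw(np.array([op.lo, op.hi]))[4]
        assert psi[1] - psi[0] == pytest.approx(1.0 / 48.0, abs=1e-8)

    def test_zero_pressures_give_zero_flow(self):
        dom = B.rectangle_channel(1.0, 4.0)
        opts = B.SolverOptions(poly_degree=8, wall_uniform=40,
                               opening_points=24)
        sol = B.solve_stokes(dom, (0.0, 0.0), opts)
        pts = np.array([0.5 + 0.2j, -1.0 - 0.3j, 1.5 + 0j])
        U, V, P, Om, psi = sol.fields_raw(pts)
        assert np.max(np.abs(U)) < 1e-12
        assert np.max(np.abs(V)) < 1e-12


class TestBifurcationSolve:
    def test_wall_velocity_vanishes(self, ref_results):
        _, sols = ref_results
        s = sols[0].problem.samples
        wall = s.bc_tag == 0
        pts = s.points[wall][::7]
        U, V, *_ = sols[0].fields_raw(pts)
        assert np.max(np.hypot(U, V)) < 1e-7

    def test_superposition_of_unit_solves(self):
        lam, mu = 0.37, -1.21
        dom = B.build_bifurcation(REF)
        sols = B.solve_stokes_multi(
            dom, [(0, 1, 0), (0, 0, 1), (0, lam, mu)], LIGHT)
        pts = np.array([-1.2 + 0.1j, 0.1 - 0.05j, 1.1 + 0.9j])
        direct = sols[2].fields_raw(pts)
        sup = sols[0].superpose(sols[1], lam, mu, (0, lam, mu))
        mixed = sup.fields_raw(pts)
        for a, b in zip(direct, mixed):
            assert np.max(np.abs(a - b)) < 1e-9

    def test_mirror_antisymmetry(self, sym_analysis):
        """In the symmetric geometry the (1,0) and (0,1) solves are mirror
        images: U even, V odd under Y -> -Y with the pressures exchanged."""
        pts = np.array([-1.0 + 0.2j, 0.3 + 0.3j, 0.9 - 0.6j])
        a = sym_analysis.sol10.fields_raw(np.conj(pts))
        b = sym_analysis.sol01.fields_raw(pts)
        assert a[0] == pytest.approx(b[0], abs=1e-6)   # U
        assert a[1] == pytest.approx(-b[1], abs=1e-6)  # V
        assert a[2] == pytest.approx(b[2], abs=1e-6)   # P

    def test_centreline_transverse_velocity_vanishes(self, sym_analysis):
        sol = sym_analysis.sol10.superpose(sym_analysis.sol01, -1.0, -1.0,
                                           (0, -1, -1))
        xs = np.linspace(-1.9, -0.3, 9)
        V = sol.fields_raw(xs + 0j)[1]
        assert np.max(np.abs(V)) < 1e-6

    def test_outside_points_flagged_nan(self, ref_results):
        _, sols = ref_results
        ff = sols[0].evaluate(np.array([0.0 + 0j, 10.0 + 10j, -1.0 + 0.2j]))
        assert not np.isnan(ff.U[0])
        assert np.isnan(ff.U[1])
        assert not np.isnan(ff.U[2])

    def test_stream_function_gradient_is_velocity(self, ref_results):
        _, sols = ref_results
        sol = sols[0]
        z = np.array([-1.1 + 0.15j, 0.4 + 0.1j])
        h = 1e-6
        U, V, *_ = sol.fields_raw(z)
        psi_yp = sol.fields_raw(z + 1j * h)[4]
        psi_ym = sol.fields_raw(z - 1j * h)[4]
        psi_xp = sol.fields_raw(z + h)[4]
        psi_xm = sol.fields_raw(z - h)[4]
        assert (psi_yp - psi_ym) / (2 * h) == pytest.approx(U, abs=1e-8)
        assert -(psi_xp - psi_xm) / (2 * h) == pytest.approx(V, abs=1e-8)

    def test_residual_degrades_with_smaller_basis(self):
        dom = B.build_bifurcation(REF)
        full = B.solve_stokes(dom, (0, -1, -1), LIGHT)
        half = B.solve_stokes(
            dom, (0, -1, -1),
            B.SolverOptions(poly_degree=6, poles_per_corner=8,
                            wall_uniform=10, opening_points=24,
                            residual_warn=1.0))
        assert (half.residual_report["overall"]
                > full.residual_report["overall"])

    def test_under_resolved_sampling_rejected(self):
        from bifstokes.rational_basis import BasisError
        dom = B.build_bifurcation(SYM)
        with pytest.raises(BasisError, match="under-resolved"):
            B.solve_stokes(dom, (0, -1, -1),
                           B.SolverOptions(poly_degree=60,
                                           poles_per_corner=60,
                                           samples_per_pole=1,
                                           wall_uniform=2,
                                           opening_points=4))
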