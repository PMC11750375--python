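"""Lightning poles, AAA Schwarz poles, Arnoldi polynomial and hole terms."""

import math

import numpy as np
import pytest

import bifstokes as B
from bifstokes.rational_basis import (SchwarzBoundaryData, aaa_schwarz_poles,
                                      arnoldi_evaluate, arnoldi_fit,
                                      lightning_poles)


class TestLightningPoles:
    def test_single_pole_at_unit_scale(self):
        p = lightning_poles(1 + 1j, 1j, N=1, sigma=4.0, scale=0.7)
        assert p.shape == (1,)
        assert abs(p[0] - (1 + 1j)) == pytest.approx(0.7)

    def test_cluster_law(self):
        corner, bis, scale = 0.5 + 0j, 1 + 0j, 1.0
        p = lightning_poles(corner, bis, N=48, sigma=4.0, scale=scale)
        d = np.abs(p - corner)
        assert np.all(np.diff(d) > 0)  # ordered outward
        assert d[-1] == pytest.approx(scale)
        # innermost distance follows exp(-sigma (sqrt(N) - 1))
        assert d[0] == pytest.approx(math.exp(-4 * (math.sqrt(48) - 1)),
                                     rel=1e-12)
        # poles lie on the bisector ray
        assert np.allclose(p.imag, corner.imag)

    def test_misdirected_bisector_rejected(self):
        from bifstokes.rational_basis import BasisError, build_basis
        dom = B.build_bifurcation(
            B.BifurcationSpec(1, 1, math.pi / 4, math.pi / 4))
        s = B.sample_boundary(dom)
        corner = dom.corners[1]
        object.__setattr__(corner, "bisector", -corner.bisector)
        with pytest.raises(BasisError, match="inside the fluid"):
            build_basis(dom, s)


class TestAAASchwarz:
    def test_line_has_entire_schwarz_function(self):
        t = np.linspace(0, 1, 64)
        z = (1 + 2j) * t + 0.3
        poles, err = aaa_schwarz_poles(SchwarzBoundaryData(z))
        assert err < 1e-10
        # conj(z) is linear in z on a line: no genuine finite poles needed;
        # any Froissart artefacts must not sit on the segment itself
        if len(poles):
            d = np.min(np.abs(poles[:, None] - z[None, :]), axis=1)
            assert np.all(d > 1e-6)

    def test_circle_pole_recovered_at_centre(self):
        c, r = 0.4 - 0.2j, 0.7
        th = np.linspace(0, 2 * math.pi, 200, endpoint=False)
        z = c + r * np.exp(1j * th)
        poles, err = aaa_schwarz_poles(SchwarzBoundaryData(z))
        assert err < 1e-8
        assert len(poles) >= 1
        assert np.min(np.abs(poles - c)) < 1e-8

    def test_too_few_samples_rejected(self):
        z = np.exp(1j * np.linspace(0, 1, 8))
        with pytest.raises(ValueError):
            aaa_schwarz_poles(SchwarzBoundaryData(z))


class TestArnoldi:
    def test_reproduces_monomial_span(self):
        rng = np.random.default_rng(0)
        Z = rng.uniform(-1, 1, 200) + 1j * rng.uniform(-1, 1, 200)
        H, Q = arnoldi_fit(Z, 12)
        # each monomial z^k must be an exact linear combination of columns
        V = np.vander(Z, 13, increasing=True)
        coef, res, *_ = np.linalg.lstsq(Q, V, rcond=None)
        assert np.max(np.abs(Q @ coef - V)) < 1e-9

    def test_derivatives_against_finite_differences(self):
        rng = np.random.default_rng(1)
        Z = np.exp(1j * np.linspace(0, 2 * math.pi, 64, endpoint=False))
        H, _ = arnoldi_fit(Z, 10)
        pts = 0.5 * (rng.uniform(-1, 1, 20) + 1j * rng.uniform(-1, 1, 20))
        W0, W1, W2 = arnoldi_evaluate(pts, H, order=2)
        h = 1e-6
        Wp = arnoldi_evaluate(pts + h, H, order=0)[0]
        Wm = arnoldi_evaluate(pts - h, H, order=0)[0]
        fd1 = (Wp - Wm) / (2 * h)
        fd2 = (Wp - 2 * W0 + Wm) / h**2
        scale = np.abs(W1).max()
        assert np.max(np.abs(W1 - fd1)) < 1e-6 * scale
        assert np.max(np.abs(W2 - fd2)) < 1e-2 * np.abs(W2).max()

    def test_constant_column(self):
        Z = np.linspace(-1, 1, 32) + 0j
        H, _ = arnoldi_fit(Z, 4)
        W0, W1 = arnoldi_evaluate(np.array([0.3 + 0.1j]), H, order=1)
        assert W0[0, 0] == pytest.approx(1.0)
        assert W1[0, 0] == pytest.approx(0.0)


class TestBasisEvaluation:
    def test_pole_column_derivative_exact(self, ref_domain):
        s = B.sample_boundary(ref_domain, poles_per_corner=4)
        basis = B.build_basis(ref_domain, s, poly_degree=4,
                              poles_per_corner=4)
        pts = np.array([0.1 + 0.05j, -1.0 + 0.2j])
        B0, B1 = basis.evaluate(pts, order=1)
        npoly = basis.poly_degree + 1
        for j, zj in enumerate(basis.poles):
            sc = basis.pole_scales[j]
            col = npoly + j
            assert B0[:, col] == pytest.approx(sc / (pts - zj))
            assert B1[:, col] == pytest.approx(-sc / (pts - zj) ** 2)

    def test_all_singularities_outside_fluid(self, ref_domain):
        s = B.sample_boundary(ref_domain)
        basis = B.build_basis(ref_domain, s)
        assert not ref_domain.contains(basis.poles).any()

    def test_log_pair_velocity_single_valued(self):
        spec = B.BifurcationSpec(1, 1, math.pi / 4, math.pi / 4,
                                 particle=(0.0, 0.0, 0.2))
        dom = B.build_bifurcation(spec)
        s = B.sample_boundary(dom, particle_points=64)
        basis = B.build_basis(dom, s, poly_degree=4, poles_per_corner=4,
                              laurent_degree=3)
        th = np.linspace(-math.pi, math.pi, 721)  # loop crossing the cut
        z = 0.35 * np.exp(1j * th)
        cols = basis.log_pair(z, order=1)[0]
        W = (-np.conj(cols["f0"]) + np.conj(z)[:, None] * cols["f1"]
             + cols["g1"])
        # velocity of each of the four real-unknown columns returns to its
        # starting value after the loop (branch-cut independence)
        assert np.max(np.abs(W[0] - W[-1])) < 1e-12
        # and is continuous across the cut (adjacent samples straddling pi)
        assert np.max(np.abs(np.diff(W, axis=0))) < 0.1
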