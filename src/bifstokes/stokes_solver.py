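"""Boundary least-squares Stokes solver in the Goursat representation.

The stream function of a 2D Stokes flow is biharmonic and can be written
``psi = Im[conj(z) f(z) + g(z)]`` with analytic Goursat functions f, g.
Velocity, pressure and vorticity follow from

    U - iV = -conj(f(z)) + conj(z) f'(z) + g'(z),
    P - i Omega = 4 f'(z).

(The velocity relation is the unique one consistent with psi above and
U = dpsi/dY, V = -dpsi/dX; see docs/methods.md for the derivation.)

Both Goursat functions are expanded in the shared rational basis; imposing
no-slip on walls and (pressure, parallel-flow) conditions at the channel
openings row-by-row yields an overdetermined real linear system solved by a
truncated-SVD least-squares factorization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.linalg import lstsq

from . import geometry as geo
from .geometry import BifurcationDomain, BoundarySampleSet, sample_boundary
from .rational_basis import RationalBasis, build_basis

__all__ = [
    "SolverOptions",
    "StokesProblem",
    "GoursatSolution",
    "FlowFields",
    "assemble_system",
    "solve_stokes",
    "solve_stokes_multi",
    "evaluate_fields",
    "boundary_residual",
]

TAG_NAMES = {geo.WALL: "wall", geo.OPENING0: "opening0",
             geo.OPENING1: "opening1", geo.OPENING2: "opening2",
             geo.PARTICLE: "particle"}


@dataclass(frozen=True)
class SolverOptions:
    """Resolution and conditioning knobs of the least-squares solve.

    The defaults reproduce the reference straight-bifurcation setup
    (degree-24 polynomial, 48 poles per corner, clustering rate sigma=4).
    """

    poly_degree: int = 24
    poles_per_corner: int = 48
    sigma: float = 4.0
    laurent_degree: int = 20
    aaa_tol: float = 1e-8
    aaa_max_terms: int = 120
    samples_per_pole: int = 3
    wall_uniform: int = 24
    opening_points: int = 48
    particle_points: int = 320
    svd_rtol: float = 1e-12
    residual_warn: float = 1e-6
    refinement: int = 4
    bc_mode: str = "pressure"  # "pressure" | "normal_stress"

    def refined(self, factor: int) -> "SolverOptions":
        return dc_replace(self,
                          samples_per_pole=self.samples_per_pole * factor,
                          wall_uniform=self.wall_uniform * factor,
                          opening_points=self.opening_points * factor,
                          particle_points=self.particle_points * factor)


# preset tuned for parameter sweeps: ~5x faster, residuals ~1e-6
FAST = SolverOptions(poly_degree=16, poles_per_corner=24, wall_uniform=12,
                     opening_points=32, particle_points=220,
                     laurent_degree=14, residual_warn=1e-4)
# preset for domains with an embedded particle (reference resolution)
PARTICLE = SolverOptions(poly_degree=80, poles_per_corner=48,
                         laurent_degree=20, opening_points=64)


@dataclass
class StokesProblem:
    domain: BifurcationDomain
    samples: BoundarySampleSet
    basis: RationalBasis
    opening_pressures: tuple  # (P0, P1, P2); P0 = 0 by convention
    options: SolverOptions

    def __post_init__(self):
        if abs(self.opening_pressures[0]) > 1e-14:
            raise ValueError("the inlet pressure is fixed to P0 = 0")


@dataclass
class FlowFields:
    """Dimensionless fields at query points; NaN outside the fluid domain."""

    points: np.ndarray
    U: np.ndarray
    V: np.ndarray
    P: np.ndarray
    Omega: np.ndarray
    Psi: np.ndarray


@dataclass
class GoursatSolution:
    """Real coefficient vector for (f, g) bound to a basis and a domain."""

    problem: StokesProblem
    coeffs: np.ndarray  # real, length 4*n_columns + 2*n_holes
    residual_report: dict = field(default_factory=dict)

    @property
    def domain(self) -> BifurcationDomain:
        return self.problem.domain

    def _compact(self):
        """Complex per-column coefficients of f and g (cached)."""
        if not hasattr(self, "_compact_cache"):
            basis = self.problem.basis
            nc = basis.n_columns
            x = self.coeffs
            cf = x[0:nc] + 1j * x[nc:2 * nc]
            cg = x[2 * nc:3 * nc] + 1j * x[3 * nc:4 * nc]
            logs = []
            for h in range(len(basis.log_centers)):
                j0 = 4 * nc + 4 * h
                a = x[j0] + 1j * x[j0 + 1]
                d = x[j0 + 2] + 1j * x[j0 + 3]
                logs.append((a, d))
            self._compact_cache = (cf, cg, logs)
        return self._compact_cache

    def goursat(self, points, order: int = 1):
        """Raw Goursat data (f, f', g, g'[, f'', g'']) at complex points."""
        if order > 1:
            return _goursat_values(self.problem.basis, self.coeffs, points,
                                   order=order)
        z = np.asarray(points, dtype=complex).ravel()
        basis = self.problem.basis
        cf, cg, logs = self._compact()
        B0, B1 = basis.evaluate(z, order=1)
        f, f1 = B0 @ cf, B1 @ cf
        g, g1 = B0 @ cg, B1 @ cg
        for (a, d), c, s in zip(logs, basis.log_centers, basis.log_scales):
            dz = z - c
            lg = np.log(dz)
            f = f + s * a * lg
            f1 = f1 + s * a / dz
            g = g + s * (-np.conj(a) * dz * (lg - 1.0) + d * lg)
            g1 = g1 + s * (-np.conj(a) * lg + d / dz)
        return [f, f1, g, g1]

    def fields_raw(self, points):
        """Field values without the inside-domain mask."""
        z = np.asarray(points, dtype=complex).ravel()
        f, f1, g, g1 = self.goursat(z)
        W = -np.conj(f) + np.conj(z) * f1 + g1
        PO = 4.0 * f1
        psi = np.imag(np.conj(z) * f + g)
        return W.real, -W.imag, PO.real, -PO.imag, psi

    def evaluate(self, points) -> FlowFields:
        """Velocity, pressure, vorticity and stream function at points.

        Points outside the closed fluid domain are flagged NaN, never an
        exception.
        """
        z = np.asarray(points, dtype=complex).ravel()
        U, V, P, Om, psi = self.fields_raw(z)
        inside = self.domain.contains(z, tol=1e-9)
        for arr in (U, V, P, Om, psi):
            arr[~inside] = np.nan
        return FlowFields(z, U, V, P, Om, psi)

    def superpose(self, other: "GoursatSolution", a: float, b: float,
                  pressures) -> "GoursatSolution":
        """Linear combination a*self + b*other sharing basis and samples."""
        prob = StokesProblem(self.problem.domain, self.problem.samples,
                             self.problem.basis, tuple(pressures),
                             self.problem.options)
        return GoursatSolution(prob, a * self.coeffs + b * other.coeffs,
                               dict(self.residual_report))


# ---------------------------------------------------------------------------
# assembly


def _contribution_matrices(basis: RationalBasis, points, order: int = 1):
    """Complex contribution of every real unknown to f, g and derivatives.

    Unknown layout: [Re f-coeffs, Im f-coeffs, Re g-coeffs, Im g-coeffs,
    (a_r, a_i) per hole log pair].  Returns dict of (npts, K) matrices
    F0, F1, G0, G1 (and F2, G2 when order >= 2).
    """
    z = np.asarray(points, dtype=complex).ravel()
    B = basis.evaluate(z, order=order)
    nc = basis.n_columns
    npts = len(z)
    K = 4 * nc + basis.n_log_unknowns
    out = {}
    names_f = ["F0", "F1", "F2"][: order + 1]
    names_g = ["G0", "G1", "G2"][: order + 1]
    for d, (nf, ng) in enumerate(zip(names_f, names_g)):
        Fm = np.zeros((npts, K), dtype=complex)
        Gm = np.zeros((npts, K), dtype=complex)
        Fm[:, 0:nc] = B[d]
        Fm[:, nc:2 * nc] = 1j * B[d]
        Gm[:, 2 * nc:3 * nc] = B[d]
        Gm[:, 3 * nc:4 * nc] = 1j * B[d]
        out[nf], out[ng] = Fm, Gm
    if basis.n_log_unknowns:
        pairs = basis.log_pair(z, order=order)
        for h, cols in enumerate(pairs):
            j0 = 4 * nc + 4 * h
            for d in range(order + 1):
                out[names_f[d]][:, j0:j0 + 4] = cols[f"f{d}"]
                out[names_g[d]][:, j0:j0 + 4] = cols[f"g{d}"]
    return out


def _velocity_matrix(z, M):
    """Complex matrix of U - iV contributions per unknown."""
    return -np.conj(M["F0"]) + np.conj(z)[:, None] * M["F1"] + M["G1"]


def assemble_system(problem: StokesProblem):
    """Weighted real least-squares matrix and right-hand side.

    Two real rows per sample: (U, V) = 0 on walls and the particle;
    (pressure, zero transverse velocity) at openings -- or (normal stress,
    zero transverse velocity) in ``bc_mode='normal_stress'``.  Rows are
    scaled by the square root of the sample's arc-length weight.
    """
    s = problem.samples
    order = 2 if problem.options.bc_mode == "normal_stress" else 1
    M = _contribution_matrices(problem.basis, s.points, order=order)
    z = s.points
    W = _velocity_matrix(z, M)
    K = W.shape[1]
    nrows = 2 * len(z)
    A = np.empty((nrows, K))
    rhs = np.zeros(nrows)

    sq = np.sqrt(s.weights)
    wallish = (s.bc_tag == geo.WALL) | (s.bc_tag == geo.PARTICLE)
    op = ~wallish

    # rows 2i / 2i+1 belong to sample i
    A[0::2][wallish] = (sq[wallish, None] * W[wallish]).real    # U = 0
    A[1::2][wallish] = -(sq[wallish, None] * W[wallish]).imag   # V = 0

    if op.any():
        t_open = 1j * s.axis[op]
        trans = (t_open[:, None] * W[op])
        if problem.options.bc_mode == "normal_stress":
            stress = _normal_stress_matrix(z[op], s.axis[op], M, op)
            A[0::2][op] = (sq[op, None] * stress).real
            rhs[0::2][op] = -sq[op] * s.bc_value[op]
        else:
            A[0::2][op] = (sq[op, None] * 4.0 * M["F1"][op]).real
            rhs[0::2][op] = sq[op] * s.bc_value[op]
        A[1::2][op] = (sq[op, None] * trans).real

    if A.shape[0] < A.shape[1]:
        raise ValueError(f"unknown count {A.shape[1]} exceeds row count "
                         f"{A.shape[0]}: increase boundary sampling")
    return A, rhs


def _normal_stress_matrix(z, axis, M, sel):
    """Rows of sigma_nn at opening samples (n = channel axis).

    sigma_nn = -P + 2 n.E.n with the strain rate E obtained from the
    Wirtinger derivatives of U - iV.
    """
    dW_dz = np.conj(z)[:, None] * M["F2"][sel] + M["G2"][sel]
    dW_dzb = M["F1"][sel] - np.conj(M["F1"][sel])
    # dW/dx = dW/dz + dW/dzbar, dW/dy = i (dW/dz - dW/dzbar), W = U - iV;
    # the unknown coefficients are real, so Re/Im stay linear in them
    Wx = dW_dz + dW_dzb
    Wy = 1j * (dW_dz - dW_dzb)
    Ux, Vx = Wx.real, -Wx.imag
    Uy, Vy = Wy.real, -Wy.imag
    n1 = axis.real[:, None]
    n2 = axis.imag[:, None]
    P = (4.0 * M["F1"][sel]).real
    e_nn = n1**2 * Ux + n1 * n2 * (Uy + Vx) + n2**2 * Vy
    return (-P + 2.0 * e_nn).astype(complex)


def _goursat_values(basis: RationalBasis, coeffs: np.ndarray, points,
                    order: int = 1):
    M = _contribution_matrices(basis, points, order=order)
    vals = [M["F0"] @ coeffs, M["F1"] @ coeffs,
            M["G0"] @ coeffs, M["G1"] @ coeffs]
    if order >= 2:
        vals += [M["F2"] @ coeffs, M["G2"] @ coeffs]
    return vals


# ---------------------------------------------------------------------------
# solving


def _solve_system(A, rhs_list, svd_rtol):
    """Column-equilibrated truncated-SVD least squares, shared factorization."""
    cn = np.linalg.norm(A, axis=0)
    cn[cn == 0] = 1.0
    Aeq = A / cn
    B = np.stack(rhs_list, axis=1)
    X, _, rank, _ = lstsq(Aeq, B, cond=svd_rtol, lapack_driver="gelsd")
    return [X[:, k] / cn for k in range(X.shape[1])], rank


def build_problem(domain: BifurcationDomain, pressures,
                  options: SolverOptions = SolverOptions()) -> StokesProblem:
    samples = sample_boundary(
        domain, poles_per_corner=options.poles_per_corner,
        sigma=options.sigma, samples_per_pole=options.samples_per_pole,
        wall_uniform=options.wall_uniform,
        opening_points=options.opening_points,
        particle_points=options.particle_points, pressures=pressures)
    basis = build_basis(domain, samples, poly_degree=options.poly_degree,
                        poles_per_corner=options.poles_per_corner,
                        sigma=options.sigma,
                        laurent_degree=options.laurent_degree,
                        aaa_tol=options.aaa_tol,
                        aaa_max_terms=options.aaa_max_terms)
    return StokesProblem(domain, samples, basis, tuple(pressures), options)


def solve_stokes_multi(domain: BifurcationDomain, pressure_sets,
                       options: SolverOptions = SolverOptions()):
    """Solve one geometry for several opening-pressure vectors at once.

    The assembly and factorization are shared; only the right-hand side
    differs between pressure sets.  Returns a list of solutions.
    """
    pressure_sets = [tuple(p) for p in pressure_sets]
    base = build_problem(domain, pressure_sets[0], options)
    A, _ = assemble_system(base)
    rhs_list = []
    for p in pressure_sets:
        prob = StokesProblem(domain, base.samples.with_pressures(p),
                             base.basis, p, options)
        _, rhs = assemble_system_rhs_only(prob, A)
        rhs_list.append(rhs)
    xs, rank = _solve_system(A, rhs_list, options.svd_rtol)
    sols = []
    for p, x in zip(pressure_sets, xs):
        prob = StokesProblem(domain, base.samples.with_pressures(p),
                             base.basis, p, options)
        sol = GoursatSolution(prob, x)
        sol.residual_report = boundary_residual(sol, options.refinement)
        sol.residual_report["rank"] = rank
        if sol.residual_report["overall"] > options.residual_warn:
            sol.residual_report["warning"] = (
                "boundary residual above "
                f"{options.residual_warn:g}")
        sols.append(sol)
    return sols


def assemble_system_rhs_only(problem: StokesProblem, A):
    """Right-hand side for a new pressure vector on an assembled system."""
    s = problem.samples
    rhs = np.zeros(A.shape[0])
    op = (s.bc_tag != geo.WALL) & (s.bc_tag != geo.PARTICLE)
    sq = np.sqrt(s.weights)
    sign = -1.0 if problem.options.bc_mode == "normal_stress" else 1.0
    rhs[0::2][op] = sign * sq[op] * s.bc_value[op]
    return A, rhs


def solve_stokes(domain: BifurcationDomain, pressures,
                 options: SolverOptions = SolverOptions()) -> GoursatSolution:
    """Sample, build the basis, assemble and solve for one pressure vector."""
    return solve_stokes_multi(domain, [pressures], options)[0]


def evaluate_fields(solution: GoursatSolution, points) -> FlowFields:
    return solution.evaluate(points)


def boundary_residual(solution: GoursatSolution, refinement: int = 4) -> dict:
    """Max boundary-condition errors on a refinement-times finer sampling."""
    prob = solution.problem
    opts = prob.options.refined(refinement)
    fine = sample_boundary(
        prob.domain, poles_per_corner=opts.poles_per_corner,
        sigma=opts.sigma, samples_per_pole=opts.samples_per_pole,
        wall_uniform=opts.wall_uniform, opening_points=opts.opening_points,
        particle_points=opts.particle_points,
        pressures=prob.opening_pressures)
    U, V, P, _, _ = solution.fields_raw(fine.points)
    report = {}
    overall = 0.0
    for tag in np.unique(fine.bc_tag):
        m = fine.bc_tag == tag
        if tag in (geo.WALL, geo.PARTICLE):
            err = max(np.max(np.abs(U[m])), np.max(np.abs(V[m])))
        else:
            perr = np.max(np.abs(P[m] - fine.bc_value[m]))
            t = 1j * fine.axis[m]
            verr = np.max(np.abs((t * (U[m] - 1j * V[m])).real))
            err = max(perr, verr)
        report[TAG_NAMES[int(tag)]] = float(err)
        overall = max(overall, err)
    report["overall"] = float(overall)
    return report
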