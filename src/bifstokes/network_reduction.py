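"""Reduction of solved Stokes flows to 0D network quantities.

A bifurcation with grounded inlet pressure (P0 = 0) maps outlet pressures
(P1, P2) linearly to outlet fluxes (Q1, Q2).  The 2x2 conductance tensor G
of that map is equivalent to a star network of three conductances
(G0, G1, G2) joined at a junction pressure Pc:

    Q = Q1 + Q2 = G0 (P0 - Pc),   Qk = Gk (Pc - Pk),
    Pc = (G1 P1 + G2 P2) / (G0 + G1 + G2).

Two Stokes solves with independent pressure vectors determine G and the
triple.  The Poiseuille reference uses the 2D channel law G~ = D^3/(12 L);
the area-preserved reference replaces each width by D^ = A/L with A the
region area from :func:`bifstokes.geometry.region_areas`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .geometry import BifurcationDomain, BifurcationSpec, region_areas
from .stokes_solver import GoursatSolution, SolverOptions, solve_stokes_multi

__all__ = [
    "FluxSet",
    "ConductanceSet",
    "ReferenceConductances",
    "channel_fluxes",
    "opening_fluxes",
    "conductance_tensor",
    "triple_to_tensor",
    "triple_from_fluxes",
    "poiseuille_reference",
    "area_preserved_reference",
    "relative_differences",
]


class ConservationError(RuntimeError):
    pass


@dataclass(frozen=True)
class FluxSet:
    """Channel fluxes: Q positive into the inlet, Q1/Q2 positive outward."""

    Q: float
    Q1: float
    Q2: float
    quadrature_gap: float = 0.0  # stream-function vs quadrature agreement

    def as_tuple(self):
        return (self.Q, self.Q1, self.Q2)


@dataclass(frozen=True)
class ConductanceSet:
    tensor: np.ndarray  # 2x2, maps (P1, P2) -> (Q1, Q2)
    triple: tuple  # (G0, G1, G2)
    junction_pressures: tuple  # (Pc for solve 1, Pc for solve 2)
    reconstruction_error: float  # relative mismatch of the star-network form

    @property
    def G0(self):
        return self.triple[0]

    @property
    def G1(self):
        return self.triple[1]

    @property
    def G2(self):
        return self.triple[2]


@dataclass(frozen=True)
class ReferenceConductances:
    triple: tuple  # (G0, G1, G2) of the reference
    tensor: np.ndarray
    effective_widths: tuple | None = None  # area-preserved only
    areas: tuple | None = None


def opening_fluxes(solution: GoursatSolution) -> list[float]:
    """Per-opening fluxes from stream-function differences at the endpoints.

    Opening 0 (the inlet) is positive into the domain; the others positive
    out of it.
    """
    dom = solution.domain
    out = []
    for op in dom.openings:
        psi = solution.fields_raw(np.array([op.lo, op.hi]))[4]
        out.append(float(psi[1] - psi[0]))
    return out


def _quadrature_fluxes(solution: GoursatSolution, n: int = 64) -> list[float]:
    dom = solution.domain
    xg, wg = np.polynomial.legendre.leggauss(n)
    out = []
    for op in dom.openings:
        a, b = op.lo, op.hi
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        z = mid + half * xg
        U, V, _, _, _ = solution.fields_raw(z)
        un = (np.conj(op.axis) * (U + 1j * V)).real
        out.append(float(np.sum(un * wg) * abs(half)))
    return out


def channel_fluxes(solution: GoursatSolution, tol: float = 1e-6) -> FluxSet:
    """Fluxes of a solved bifurcation with a mass-conservation check.

    The stream-function construction is cross-checked against 64-point
    Gauss quadrature of the normal velocity on each opening.
    """
    qs = opening_fluxes(solution)
    if len(qs) != 3:
        raise ValueError("channel_fluxes expects a three-opening bifurcation")
    quad = _quadrature_fluxes(solution)
    gap = max(abs(a - b) for a, b in zip(qs, quad))
    Q, Q1, Q2 = qs
    if abs(Q - Q1 - Q2) > tol * max(1.0, abs(Q)):
        raise ConservationError(
            f"mass conservation violated: Q={Q:.3e}, Q1={Q1:.3e}, "
            f"Q2={Q2:.3e}, defect={Q - Q1 - Q2:.3e}")
    return FluxSet(Q, Q1, Q2, gap)


def triple_to_tensor(G0: float, G1: float, G2: float) -> np.ndarray:
    """The star-network conductance tensor for a triple (G0, G1, G2)."""
    s = G0 + G1 + G2
    return np.array([
        [-G1 * (G2 + G0) / s, G1 * G2 / s],
        [G1 * G2 / s, -G2 * (G1 + G0) / s],
    ])


def triple_from_fluxes(flux1: FluxSet, flux2: FluxSet,
                       degeneracy_tol: float = 1e-9):
    """Recover (G0, G1, G2) and junction pressures from the two unit solves.

    ``flux1``/``flux2`` correspond to P = (1, 0) and P = (0, 1).  The closed
    form follows from the star-network relations; if its denominator nearly
    cancels, a nonlinear least-squares fit of the star model to the four
    fluxes (initialized at the closed form) is used instead.
    """
    Qi1, Q11, Q21 = flux1.as_tuple()
    Qi2, Q12, Q22 = flux2.as_tuple()
    r = Qi2 / Qi1
    den = Q12 - r * Q11
    degenerate = abs(den) < degeneracy_tol * max(abs(Q12), abs(r * Q11))
    if degenerate:
        # all-equal star initializer: off-diagonal of the tensor is G/3 there
        g = 3.0 * abs(Q12)
        triple = (g, g, g)
        Pc1 = Pc2 = float("nan")
    else:
        Pc1 = Q12 / den
        Pc2 = r * Pc1
        G1 = Q12 / Pc2
        G2 = Q21 / Pc1
        G0 = -Qi1 / Pc1
        triple = (G0, G1, G2)

    def model_residual(g):
        T = triple_to_tensor(*g)
        pred1 = T @ np.array([1.0, 0.0])
        pred2 = T @ np.array([0.0, 1.0])
        return np.array([pred1[0] - Q11, pred1[1] - Q21,
                         pred2[0] - Q12, pred2[1] - Q22])

    res = np.max(np.abs(model_residual(np.array(triple))))
    scale = max(abs(Q11), abs(Q22))
    if degenerate or res > 1e-8 * scale:
        fit = least_squares(model_residual, np.array(triple), method="lm")
        triple = tuple(fit.x)
        res = np.max(np.abs(model_residual(fit.x)))
        s = sum(triple)
        Pc1, Pc2 = triple[1] / s, triple[2] / s
    return triple, (Pc1, Pc2), res / scale


def conductance_tensor(domain: BifurcationDomain,
                       options: SolverOptions = SolverOptions(),
                       return_solutions: bool = False):
    """Measure the conductance tensor and triple of a bifurcation.

    Runs two Stokes solves with P = (1, 0) and P = (0, 1) (shared
    factorization), reads off the tensor columns from the outlet fluxes, and
    recovers the triple.  The star-network reconstruction of the tensor is
    asserted to match the measured tensor.
    """
    sols = solve_stokes_multi(domain, [(0.0, 1.0, 0.0), (0.0, 0.0, 1.0)],
                              options)
    # conservation can only hold to the level the walls are resolved
    tol = max(1e-6, 10.0 * max(s.residual_report["overall"] for s in sols))
    f1 = channel_fluxes(sols[0], tol=tol)
    f2 = channel_fluxes(sols[1], tol=tol)
    tensor = np.array([[f1.Q1, f2.Q1], [f1.Q2, f2.Q2]])
    triple, pcs, rec = triple_from_fluxes(f1, f2)
    recon = triple_to_tensor(*triple)
    rel = np.max(np.abs(recon - tensor)) / np.max(np.abs(tensor))
    rel_tol = max(1e-4, 30.0 * max(s.residual_report["overall"]
                                   for s in sols))
    if rel > rel_tol:
        raise RuntimeError(
            "star-network reconstruction disagrees with the measured tensor "
            f"(relative error {rel:.2e}): the Stokes solves look unconverged")
    cond = ConductanceSet(tensor, triple, pcs, rel)
    if return_solutions:
        return cond, sols
    return cond


def poiseuille_reference(spec: BifurcationSpec | None = None, *,
                         D1: float | None = None, D2: float | None = None,
                         L: float | None = None) -> ReferenceConductances:
    """Poiseuille-law conductances G~ = D^3/(12 L) and the network tensor."""
    if spec is not None:
        D1, D2, L = spec.D1, spec.D2, spec.L
    triple = (1.0 / (12 * L), D1**3 / (12 * L), D2**3 / (12 * L))
    return ReferenceConductances(triple, triple_to_tensor(*triple))


def area_preserved_reference(domain: BifurcationDomain) -> ReferenceConductances:
    """Area-preserved conductances G^ with effective widths D^ = A / L.

    Region areas exclude any particle, so the reference captures area
    changes (curved walls, particle blockage) while still assuming
    unidirectional Poiseuille flow.
    """
    A = region_areas(domain)
    L = domain.spec.L
    D_hat = tuple(a / L for a in A)
    triple = tuple(d**3 / (12 * L) for d in D_hat)
    return ReferenceConductances(triple, triple_to_tensor(*triple),
                                 effective_widths=D_hat, areas=A)


def relative_differences(computed: ConductanceSet,
                         reference: ReferenceConductances) -> tuple:
    """Per-channel 100 (G_i - ref_i)/ref_i, from unrounded values."""
    return tuple(100.0 * (g - r) / r
                 for g, r in zip(computed.triple, reference.triple))
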