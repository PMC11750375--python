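"""Flow partition and streamline topology of a bifurcation.

All operations here work at fixed inlet flux Q = 1: the outlet pressures
(P1, P2) are chosen to realize a prescribed difference dP = P1 - P2 while
the conductance tensor constrains the total outlet flux to one.  Because
Stokes flow is linear, every such flow is a superposition of the two cached
unit-pressure solves -- no new boundary solve is needed per dP.

The *reversal threshold* dP* is the pressure difference at which the flux in
child channel 1 changes sign; the *separatrix* is the streamline dividing
inlet fluid destined for channel 1 from fluid destined for channel 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .geometry import BifurcationDomain
from .network_reduction import (ConductanceSet, channel_fluxes,
                                conductance_tensor, poiseuille_reference)
from .stokes_solver import GoursatSolution, SolverOptions

__all__ = [
    "ConstrainedFlow",
    "Streamline",
    "BifurcationFlowAnalysis",
    "constrained_flow",
    "reversal_threshold",
    "trace_streamline",
    "separatrix",
]


@dataclass
class ConstrainedFlow:
    delta_p: float
    pressures: tuple  # (P1, P2) realizing delta_p at unit inlet flux
    solution: GoursatSolution
    partition: tuple  # (Q1, Q2), Q1 + Q2 = 1


@dataclass
class Streamline:
    vertices: np.ndarray  # complex polyline
    psi_level: float
    terminus: str  # opening0 | opening1 | opening2 | corner | stagnation
    psi_drift: float = 0.0


class BifurcationFlowAnalysis:
    """Caches the two unit-pressure solves of one geometry for reuse."""

    def __init__(self, domain: BifurcationDomain,
                 options: SolverOptions = SolverOptions(),
                 base=None):
        self.domain = domain
        self.options = options
        if base is None:
            base = conductance_tensor(domain, options, return_solutions=True)
        self.conductances, (self.sol10, self.sol01) = base

    @property
    def tensor(self) -> np.ndarray:
        return self.conductances.tensor

    def pressures_for(self, delta_p: float) -> tuple:
        """(P1, P2) with P1 - P2 = delta_p and unit total outlet flux."""
        T = self.tensor
        s1, s2 = T[0, 0] + T[1, 0], T[0, 1] + T[1, 1]
        if abs(s1 + s2) < 1e-14:
            raise RuntimeError("degenerate conductance tensor")
        P2 = (1.0 - s1 * delta_p) / (s1 + s2)
        return (P2 + delta_p, P2)

    def constrained_flow(self, delta_p: float) -> ConstrainedFlow:
        P1, P2 = self.pressures_for(delta_p)
        sol = self.sol10.superpose(self.sol01, P1, P2, (0.0, P1, P2))
        fx = channel_fluxes(sol)
        if abs(fx.Q - 1.0) > 1e-6:
            raise RuntimeError(f"inlet flux {fx.Q} deviates from 1")
        return ConstrainedFlow(delta_p, (P1, P2), sol, (fx.Q1, fx.Q2))

    def reversal_threshold(self) -> float:
        """dP* where Q1 vanishes at unit inlet flux, from the tensor."""
        return _threshold_from_tensor(self.tensor, verify=True)

    def poiseuille_threshold(self) -> float:
        spec = self.domain.spec
        ref = poiseuille_reference(spec)
        return _threshold_from_tensor(ref.tensor, verify=False)


def _threshold_from_tensor(T: np.ndarray, verify: bool = False) -> float:
    # Q1 = 0 fixes the pressure direction (P1, P2) ~ (-G12, G11); the unit
    # inlet flux fixes the magnitude.
    s1, s2 = T[0, 0] + T[1, 0], T[0, 1] + T[1, 1]
    P1, P2 = -T[0, 1], T[0, 0]
    denom = s1 * P1 + s2 * P2
    if abs(denom) < 1e-300:
        raise RuntimeError("conductance tensor admits no unit-flux reversal")
    dp_star = (P1 - P2) / denom

    if verify:
        def q1(dp):
            p2 = (1.0 - s1 * dp) / (s1 + s2)
            p1 = p2 + dp
            return T[0, 0] * p1 + T[0, 1] * p2

        lo, hi = dp_star - max(1.0, 0.1 * abs(dp_star)), \
            dp_star + max(1.0, 0.1 * abs(dp_star))
        if q1(lo) * q1(hi) > 0:
            raise RuntimeError(
                f"no sign change of Q1 in [{lo:.3g}, {hi:.3g}]")
        bracket = brentq(q1, lo, hi, xtol=1e-12)
        if abs(bracket - dp_star) > 1e-8 * max(1.0, abs(dp_star)):
            raise RuntimeError("closed-form threshold fails the bracket check")
    return dp_star


def constrained_flow(domain: BifurcationDomain, delta_p: float,
                     options: SolverOptions = SolverOptions(),
                     base: BifurcationFlowAnalysis | None = None):
    ana = base or BifurcationFlowAnalysis(domain, options)
    return ana.constrained_flow(delta_p)


def reversal_threshold(domain: BifurcationDomain,
                       options: SolverOptions = SolverOptions(),
                       base: BifurcationFlowAnalysis | None = None):
    """(Stokes dP*, Poiseuille dP*) for reversal of child channel 1."""
    ana = base or BifurcationFlowAnalysis(domain, options)
    return ana.reversal_threshold(), ana.poiseuille_threshold()


# ---------------------------------------------------------------------------
# streamlines


def trace_streamline(solution: GoursatSolution, start: complex,
                     rtol: float = 1e-9, atol: float = 1e-11,
                     max_time: float = 5000.0,
                     reverse: bool = False) -> Streamline:
    """Integrate the velocity field from ``start`` until an opening or
    stagnation is reached.

    Uses adaptive Runge-Kutta (RK45) on dz/dt = U + iV; the stream function
    is constant along the path and its drift is recorded as a self-check.
    """
    dom = solution.domain
    z0 = complex(start)
    if not dom.contains(np.array([z0]))[0]:
        raise ValueError("start point lies outside the fluid domain")
    psi0 = float(solution.fields_raw(np.array([z0]))[4][0])
    sgn = -1.0 if reverse else 1.0

    def rhs(t, y):
        z = complex(y[0], y[1])
        U, V, _, _, _ = solution.fields_raw(np.array([z]))
        return [sgn * U[0], sgn * V[0]]

    events = []
    margin = 1e-7
    for op in dom.openings:
        if op.index == 0:
            def ev(t, y, op=op):
                return y[0] - (op.center.real + margin)
        else:
            def ev(t, y, op=op):
                s = (np.conj(op.axis)
                     * (complex(y[0], y[1]) - 0j)).real
                return abs(op.center) - margin - s
        ev.terminal = True
        events.append(ev)

    stall_speed = 1e-7

    def slow(t, y):
        u = rhs(t, y)
        return math.hypot(u[0], u[1]) - stall_speed
    slow.terminal = True
    events.append(slow)

    # streamlines at a wall stream-function level terminate on the wall;
    # stop once the path is within wall_eps of the boundary (but only after
    # it has left the start neighbourhood, which may itself touch a wall)
    wall_eps = 3e-4
    boundary = dom.polygon.boundary

    def near_wall(t, y, _armed=[False]):
        from shapely.geometry import Point as _P
        d = boundary.distance(_P(y[0], y[1]))
        if not _armed[0]:
            if d > 10 * wall_eps:
                _armed[0] = True
            return 1.0
        return d - wall_eps
    near_wall.terminal = True
    events.append(near_wall)

    res = solve_ivp(rhs, (0.0, max_time), [z0.real, z0.imag], rtol=rtol,
                    atol=atol, events=events, dense_output=False,
                    max_step=0.25)
    zs = res.y[0] + 1j * res.y[1]
    terminus = "stagnation"
    for k, te in enumerate(res.t_events[:len(dom.openings)]):
        if len(te):
            terminus = f"opening{k}"
    if terminus == "stagnation":
        hit_wall = len(res.t_events[len(dom.openings) + 1]) > 0
        speed = abs(complex(*rhs(0.0, [zs[-1].real, zs[-1].imag])))
        if not hit_wall and speed > 10 * stall_speed:
            terminus = "interrupted"
        else:
            corners = [c.point for c in dom.corners]
            if corners and min(abs(zs[-1] - c) for c in corners) < 0.05:
                terminus = "corner"
    psi = solution.fields_raw(zs)[4]
    drift = float(np.nanmax(np.abs(psi - psi0)))
    return Streamline(zs, psi0, terminus, drift)


def centre_streamline(solution: GoursatSolution,
                      offset: float = 1e-6) -> Streamline:
    """The streamline bisecting the inlet flux (the parent centre line)."""
    dom = solution.domain
    inlet = dom.openings[0]
    psi_lo, psi_hi = solution.fields_raw(
        np.array([inlet.lo, inlet.hi]))[4]
    level = 0.5 * (psi_lo + psi_hi)
    y0 = _inlet_ordinate(solution, level)
    start = complex(inlet.center.real + offset, y0)
    return trace_streamline(solution, start)


def _inlet_ordinate(solution: GoursatSolution, level: float) -> float:
    dom = solution.domain
    inlet = dom.openings[0]
    x = inlet.center.real
    half = inlet.width / 2

    def f(y):
        return float(solution.fields_raw(
            np.array([complex(x, y)]))[4][0]) - level

    eps = 1e-9 * inlet.width
    return brentq(f, -half + eps, half - eps, xtol=1e-12)


def separatrix(flow: ConstrainedFlow, offset: float = 1e-6):
    """The separating streamline and its inlet split ordinate Y*.

    For forward flow (0 < Q1 < 1) the dividing streamline carries the stream
    function level psi(inlet bottom corner) + Q2: the inlet flux below it is
    exactly Q2 (bound for channel 2) and above it Q1.  Returns
    (Streamline, Y*).  For reversed channel-1 flow the level equals the
    upper-wall value and the streamline is traced backwards from the
    channel-1 opening, where the reversed fluid enters.
    """
    sol = flow.solution
    dom = sol.domain
    Q1, Q2 = flow.partition
    if abs(Q1) < 1e-8:
        raise RuntimeError("flow sits at the reversal threshold; "
                           "use the threshold computation instead")
    inlet = dom.openings[0]
    psi_lo, psi_hi = sol.fields_raw(np.array([inlet.lo, inlet.hi]))[4]
    if Q1 > 0:
        level = float(psi_lo) + Q2
        y_star = _inlet_ordinate(sol, level)
        start = complex(inlet.center.real + offset, y_star)
        line = trace_streamline(sol, start)
        return line, y_star
    # reversed: fluid enters through openings 0 and 1 and all leaves through
    # opening 2.  The dividing level is the upper-wall stream function; it
    # detaches from the upper wall at a stagnation point.  Anchor on the
    # channel-2 opening, where the level is attained strictly inside, and
    # trace backwards toward the detachment point.
    level = float(psi_hi)
    op2 = dom.openings[2]

    def f(t):
        z = op2.lo + t * (op2.hi - op2.lo)
        return float(sol.fields_raw(np.array([z]))[4][0]) - level

    t_star = brentq(f, 1e-9, 1 - 1e-9, xtol=1e-12)
    z0 = op2.lo + t_star * (op2.hi - op2.lo) - offset * op2.axis
    line = trace_streamline(sol, z0, reverse=True)
    return line, t_star


def inlet_flux_below(solution: GoursatSolution, y_star: float,
                     n: int = 256) -> float:
    """Quadrature of U over the inlet below Y*: the flux bound for child 2."""
    dom = solution.domain
    inlet = dom.openings[0]
    x = inlet.center.real
    half = inlet.width / 2
    xg, wg = np.polynomial.legendre.leggauss(n)
    ys = -half + (y_star + half) * 0.5 * (xg + 1.0)
    U = solution.fields_raw(x + 1j * ys)[0]
    return float(np.sum(U * wg) * 0.5 * (y_star + half))
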