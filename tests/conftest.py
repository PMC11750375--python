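"""Shared fixtures: the heavy Stokes solves are session-scoped so the
reference geometry, the symmetric bifurcation and the particle cases are
each solved once for the whole suite."""

import math

import numpy as np
import pytest

import bifstokes as B
from bifstokes.flow_analysis import BifurcationFlowAnalysis

REF = B.BifurcationSpec(D1=0.9, D2=0.8, alpha=math.pi / 4,
                        beta=math.pi / 3, L=2.0)
SYM = B.BifurcationSpec(D1=1.0, D2=1.0, alpha=math.pi / 4,
                        beta=math.pi / 4, L=2.0)

# light resolution for tests that only need qualitative behaviour
LIGHT = B.SolverOptions(poly_degree=12, poles_per_corner=16, wall_uniform=10,
                        opening_points=24, particle_points=160,
                        laurent_degree=10, residual_warn=1.0)


@pytest.fixture(scope="session")
def ref_domain():
    return B.build_bifurcation(REF)


@pytest.fixture(scope="session")
def ref_results(ref_domain):
    """Full-resolution conductance tensor + solutions of the reference case."""
    cond, sols = B.conductance_tensor(ref_domain, B.SolverOptions(),
                                      return_solutions=True)
    return cond, sols


@pytest.fixture(scope="session")
def sym_domain():
    return B.build_bifurcation(SYM)


@pytest.fixture(scope="session")
def sym_analysis(sym_domain):
    return BifurcationFlowAnalysis(sym_domain, B.SolverOptions())


@pytest.fixture(scope="session")
def particle_tensor_r02():
    spec = B.BifurcationSpec(D1=1, D2=1, alpha=math.pi / 4, beta=math.pi / 4,
                             L=2.0, particle=(0.0, 0.0, 0.2))
    dom = B.build_bifurcation(spec)
    return B.conductance_tensor(dom, B.PARTICLE)


@pytest.fixture(scope="session")
def particle_tensor_r01():
    spec = B.BifurcationSpec(D1=1, D2=1, alpha=math.pi / 4, beta=math.pi / 4,
                             L=2.0, particle=(0.0, 0.0, 0.1))
    dom = B.build_bifurcation(spec)
    return B.conductance_tensor(dom, B.PARTICLE)


@pytest.fixture(scope="session")
def particle_offcentre():
    """Cylinder on the child-1 centreline, one width from the junction."""
    x0 = math.cos(math.pi / 4)
    spec = B.BifurcationSpec(D1=1, D2=1, alpha=math.pi / 4, beta=math.pi / 4,
                             L=2.0, particle=(x0, x0, 0.2))
    dom = B.build_bifurcation(spec)
    return dom, B.conductance_tensor(dom, B.PARTICLE)


@pytest.fixture(scope="session")
def sweep_grid():
    """6x6 child-width grid at alpha=beta=pi/4 (sweep resolution)."""
    vals = np.linspace(0.5, 1.0, 6)
    out = {}
    for d1 in vals:
        for d2 in vals:
            spec = B.BifurcationSpec(D1=float(d1), D2=float(d2),
                                     alpha=math.pi / 4, beta=math.pi / 4,
                                     L=2.0)
            dom = B.build_bifurcation(spec)
            out[(round(float(d1), 3), round(float(d2), 3))] = \
                B.conductance_tensor(dom, B.FAST)
    return out
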