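"""Dimensionless bifurcation geometry.

A bifurcation consists of one parent channel of unit width whose centreline
runs along the negative X axis, and two child channels of widths ``D1`` and
``D2`` whose centrelines leave the origin at angles ``+alpha`` (upper child)
and ``-beta`` (lower child) from the positive X axis.  Every channel has
centreline length ``L``.  All lengths are scaled on the parent width; the
:class:`DimensionalScales` type is the only place dimensional quantities
appear.

The boundary is traversed counter-clockwise (fluid on the left), starting at
the upper inlet corner.  Walls may be straight polylines meeting at three
reentrant corners, or cubic Bezier arcs tangent to the straight channel walls
at the openings.  A circular hole ("particle") may be embedded in the fluid.
"""

from __future__ import annotations

import cmath
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

__all__ = [
    "DimensionalScales",
    "BifurcationSpec",
    "BifurcationDomain",
    "BoundarySampleSet",
    "GeometryError",
    "ValidityReport",
    "build_bifurcation",
    "validate_spec",
    "sample_boundary",
    "region_areas",
    "rectangle_channel",
]

_PARALLEL_TOL = 1e-12
_FLAT_ANGLE_TOL = 1e-9

WALL, OPENING0, OPENING1, OPENING2, PARTICLE = 0, 1, 2, 3, 4
OPENING_TAGS = (OPENING0, OPENING1, OPENING2)


class GeometryError(ValueError):
    """Raised when a requested geometry violates a named predicate."""

    def __init__(self, violations):
        self.violations = tuple(violations)
        super().__init__("invalid geometry: " + "; ".join(self.violations))


@dataclass(frozen=True)
class DimensionalScales:
    """Dimensional scales used to map dimensionless results back to physical units.

    Parameters
    ----------
    d : parent channel width (length units).
    q : inlet flux (area/time in 2D).
    mu : dynamic viscosity.

    Lengths scale with ``d``, velocities with ``q/d``, pressures with
    ``mu q / d**2`` and conductances (flux per pressure drop) with
    ``d**2 / mu``.  The solver itself never sees these numbers.
    """

    d: float
    q: float
    mu: float

    def __post_init__(self):
        if not (self.d > 0 and self.q > 0 and self.mu > 0):
            raise ValueError("d, q and mu must all be strictly positive")

    @property
    def length(self) -> float:
        return self.d

    @property
    def velocity(self) -> float:
        return self.q / self.d

    @property
    def pressure(self) -> float:
        return self.mu * self.q / self.d**2

    @property
    def conductance(self) -> float:
        return self.d**2 / self.mu


@dataclass(frozen=True)
class BifurcationSpec:
    """Dimensionless parameters of a single bifurcation."""

    D1: float = 1.0
    D2: float = 1.0
    alpha: float = math.pi / 4
    beta: float = math.pi / 4
    L: float = 2.0
    wall_kind: str = "straight"  # "straight" | "bezier"
    particle: tuple[float, float, float] | None = None  # (X0, Y0, R)
    bezier_control_fraction: float = 1.0

    def swapped(self) -> "BifurcationSpec":
        """Exchange the two children: (D1, alpha) <-> (D2, beta)."""
        part = self.particle
        if part is not None:
            part = (part[0], -part[1], part[2])
        return replace(self, D1=self.D2, D2=self.D1, alpha=self.beta,
                       beta=self.alpha, particle=part)


@dataclass(frozen=True)
class ValidityReport:
    ok: bool
    violations: tuple[str, ...]


@dataclass(frozen=True)
class Segment:
    a: complex
    b: complex

    @property
    def length(self) -> float:
        return abs(self.b - self.a)

    def point(self, t):
        t = np.asarray(t, dtype=float)
        return self.a + t * (self.b - self.a)

    def tangent(self, t):
        t = np.asarray(t, dtype=float)
        d = (self.b - self.a) / abs(self.b - self.a)
        return np.full(t.shape, d, dtype=complex)


@dataclass(frozen=True)
class Bezier:
    """Cubic Bezier arc p0..p3, traversed for t in [0, 1]."""

    p0: complex
    p1: complex
    p2: complex
    p3: complex

    def point(self, t):
        t = np.asarray(t, dtype=float)
        s = 1.0 - t
        return (s**3 * self.p0 + 3 * s**2 * t * self.p1
                + 3 * s * t**2 * self.p2 + t**3 * self.p3)

    def derivative(self, t):
        t = np.asarray(t, dtype=float)
        s = 1.0 - t
        return (3 * s**2 * (self.p1 - self.p0)
                + 6 * s * t * (self.p2 - self.p1)
                + 3 * t**2 * (self.p3 - self.p2))

    def tangent(self, t):
        d = self.derivative(t)
        d = np.where(np.abs(d) < 1e-14, self.p3 - self.p0, d)
        return d / np.abs(d)


@dataclass(frozen=True)
class WallPiece:
    """One boundary curve between two opening corners (or corner anchors).

    ``cluster_start``/``cluster_end`` reference the index into
    ``domain.corners`` of a reentrant corner located at that end of the
    piece, so that boundary sampling can cluster there.
    """

    curve: Segment | Bezier
    cluster_start: int | None = None
    cluster_end: int | None = None


@dataclass(frozen=True)
class Opening:
    """A straight channel opening carrying a pressure boundary condition.

    ``axis`` is the unit channel direction oriented with forward flow
    (into the domain at the inlet, out of it at the children), so the flux
    through the opening, positive in the forward direction, is
    ``psi(hi) - psi(lo)``.
    """

    index: int
    center: complex
    axis: complex
    width: float

    @property
    def lo(self) -> complex:
        return self.center - 0.5j * self.width * self.axis

    @property
    def hi(self) -> complex:
        return self.center + 0.5j * self.width * self.axis

    @property
    def outward_normal(self) -> complex:
        return -self.axis if self.index == 0 else self.axis


@dataclass(frozen=True)
class Corner:
    """A wall corner: reentrant corners carry a pole-cluster direction."""

    point: complex
    interior_angle: float
    reentrant: bool
    bisector: complex | None  # unit vector into the solid, None if flat
    pole_scale: float  # min distance from the corner to the adjacent openings


@dataclass(frozen=True)
class ParticleSpec:
    center: complex
    radius: float


@dataclass
class BifurcationDomain:
    """A constructed flow domain (bifurcation or plain channel)."""

    spec: BifurcationSpec | None
    walls: list[WallPiece]
    openings: list[Opening]
    corners: list[Corner]
    particle: ParticleSpec | None
    polygon: Polygon  # fluid region, hole removed if a particle is present
    region_anchors: list[complex] = field(default_factory=list)
    region_polygons: list[Polygon] = field(default_factory=list)

    def contains(self, pts, tol: float = 0.0) -> np.ndarray:
        """Vectorized membership test for complex points (closed domain)."""
        pts = np.atleast_1d(np.asarray(pts, dtype=complex))
        inside = shapely.contains_xy(self.polygon, pts.real, pts.imag)
        if tol > 0:
            for i in np.nonzero(~inside)[0]:
                if self.polygon.distance(Point(pts[i].real, pts[i].imag)) <= tol:
                    inside[i] = True
        return inside

    @property
    def fluid_area(self) -> float:
        return self.polygon.area


@dataclass
class BoundarySampleSet:
    """Collocation samples on the domain boundary.

    ``normals`` point out of the fluid; ``tangents`` follow the
    counter-clockwise boundary traversal (clockwise around a hole).
    ``bc_value`` holds the prescribed opening pressure (NaN elsewhere) and
    ``axis`` the forward channel direction for opening samples.
    """

    points: np.ndarray
    weights: np.ndarray
    tangents: np.ndarray
    normals: np.ndarray
    bc_tag: np.ndarray
    bc_value: np.ndarray
    axis: np.ndarray
    piece_id: np.ndarray

    def __len__(self) -> int:
        return len(self.points)

    def with_pressures(self, pressures) -> "BoundarySampleSet":
        """Return a copy with opening pressures (P0, P1, P2) installed."""
        bc = np.full(len(self.points), np.nan)
        for tag, p in zip(OPENING_TAGS, pressures):
            bc[self.bc_tag == tag] = p
        return BoundarySampleSet(self.points, self.weights, self.tangents,
                                 self.normals, self.bc_tag, bc, self.axis,
                                 self.piece_id)


# ---------------------------------------------------------------------------
# wall-line algebra


def _intersect_lines(p1: complex, d1: complex, p2: complex, d2: complex):
    """Intersection of two lines given by point + unit direction.

    Returns (point, kind) with kind in {"point", "coincident", "parallel"}.
    For coincident lines the returned point is the foot of the origin on the
    common line (the degenerate flat-corner convention).
    """
    cross = (d1.conjugate() * d2).imag
    if abs(cross) < _PARALLEL_TOL:
        # distance from p2 to line 1
        off = (d1.conjugate() * (p2 - p1)).imag
        if abs(off) < 1e-9:
            foot = p1 + (d1.conjugate() * (0 - p1)).real * d1
            return foot, "coincident"
        return None, "parallel"
    t = (d2.conjugate() * (p2 - p1)).imag / (d2.conjugate() * d1).imag
    return p1 + t * d1, "point"


def _corner_geometry(point: complex, d_in: complex, d_out: complex,
                     openings: list[Opening]) -> Corner:
    """Classify a corner from the CCW traversal tangents on either side."""
    turn = cmath.phase(d_out / d_in)
    interior = math.pi - turn
    reentrant = turn < -_FLAT_ANGLE_TOL
    bisector = None
    if reentrant:
        b = d_out - d_in
        bisector = b / abs(b)
    scale = min(_distance_to_opening(point, op) for op in openings)
    return Corner(point, interior, reentrant, bisector, max(scale, 1e-6))


def _distance_to_opening(p: complex, op: Opening) -> float:
    a, b = op.lo, op.hi
    t = ((b - a).conjugate() * (p - a)).real / abs(b - a) ** 2
    t = min(max(t, 0.0), 1.0)
    return abs(a + t * (b - a) - p)


# ---------------------------------------------------------------------------
# spec validation


def _wall_lines(spec: BifurcationSpec):
    e1 = cmath.exp(1j * spec.alpha)
    e2 = cmath.exp(-1j * spec.beta)
    return {
        "parent_upper": (0.5j, 1.0 + 0j),
        "parent_lower": (-0.5j, 1.0 + 0j),
        "child1_upper": (0.5j * spec.D1 * e1, e1),
        "child1_lower": (-0.5j * spec.D1 * e1, e1),
        "child2_upper": (0.5j * spec.D2 * e2, e2),
        "child2_lower": (-0.5j * spec.D2 * e2, e2),
    }


def _straight_corners(spec: BifurcationSpec):
    """The three wall-line intersection points A (top), B (middle), C (bottom).

    Returns (points, violations); points may contain None on failure.
    """
    lines = _wall_lines(spec)
    pairs = [
        ("corner A", "parent_upper", "child1_upper"),
        ("corner B", "child1_lower", "child2_upper"),
        ("corner C", "parent_lower", "child2_lower"),
    ]
    pts, violations = [], []
    for name, la, lb in pairs:
        p, kind = _intersect_lines(*lines[la], *lines[lb])
        if kind == "parallel":
            violations.append(f"{name}: wall lines {la} and {lb} are parallel "
                              "and distinct (no wall intersection exists)")
        pts.append(p)
    return pts, violations


def validate_spec(spec: BifurcationSpec) -> ValidityReport:
    """Check a bifurcation spec against the admissibility predicates.

    Always returns a report; never raises.
    """
    v: list[str] = []
    if not (0 < spec.D1 <= 1 and 0 < spec.D2 <= 1):
        v.append("child widths must satisfy 0 < D1, D2 <= 1")
    if not (-1e-12 <= spec.alpha <= math.pi / 2 + 1e-12
            and -1e-12 <= spec.beta <= math.pi / 2 + 1e-12):
        v.append("angles must lie in [0, pi/2]")
    if not spec.L > 0:
        v.append("L must be positive")
    if spec.wall_kind not in ("straight", "bezier"):
        v.append(f"unknown wall_kind {spec.wall_kind!r}")
    if not (0 < spec.bezier_control_fraction <= 1):
        v.append("bezier_control_fraction must lie in (0, 1]")
    if v:
        return ValidityReport(False, tuple(v))

    if spec.alpha + spec.beta < math.pi / 2 - 1e-9:
        # the inter-child wedge narrows below a right angle: the children
        # overlap at unit widths and otherwise leave a small-angle sliver
        v.append("child channels overlap or pinch a small angle "
                 "(alpha + beta < pi/2)")

    pts, pv = _straight_corners(spec)
    v.extend(pv)
    if not v:
        A, B, C = pts
        e1 = cmath.exp(1j * spec.alpha)
        e2 = cmath.exp(-1j * spec.beta)
        L = spec.L
        margin = 1e-9
        checks = [
            ("corner A", A, [(1.0, "parent"), (e1, "child 1")]),
            ("corner B", B, [(e1, "child 1"), (e2, "child 2")]),
            ("corner C", C, [(1.0, "parent"), (e2, "child 2")]),
        ]
        for name, p, axes in checks:
            for ax, chan in axes:
                proj = (ax.conjugate() * p).real
                if abs(proj) > L - margin:
                    v.append(f"{name} falls outside centreline distance L "
                             f"from the origin along the {chan} axis")
        if not v:
            try:
                poly = _boundary_polygon(spec, pts)
                if not poly.is_valid or not poly.is_simple:
                    v.append("boundary curve self-intersects")
            except Exception as exc:  # defensive: malformed chain
                v.append(f"boundary construction failed: {exc}")

    if not v and spec.particle is not None:
        x0, y0, r = spec.particle
        if not r > 0:
            v.append("particle radius must be positive")
        else:
            poly = _boundary_polygon(spec, _straight_corners(spec)[0])
            disc = Point(x0, y0).buffer(r, quad_segs=64)
            clearance = poly.exterior.distance(Point(x0, y0)) - r
            if not poly.contains(Point(x0, y0)) or clearance <= 1e-3:
                v.append("particle is not strictly inside the fluid domain "
                         "(clearance <= 1e-3)")
            elif not poly.contains(disc):
                v.append("particle intersects the channel boundary")

    return ValidityReport(not v, tuple(v))


# ---------------------------------------------------------------------------
# domain construction


def _opening_list(spec: BifurcationSpec) -> list[Opening]:
    e1 = cmath.exp(1j * spec.alpha)
    e2 = cmath.exp(-1j * spec.beta)
    L = spec.L
    return [
        Opening(0, complex(-L, 0), 1.0 + 0j, 1.0),
        Opening(1, L * e1, e1, spec.D1),
        Opening(2, L * e2, e2, spec.D2),
    ]


def _wall_chain(spec: BifurcationSpec, corners_pts):
    """CCW chain of wall pieces with the corner index adjacent to each end.

    Corner order in the returned corner-point list is [C, B, A] following the
    traversal; pieces reference these indices.
    """
    A, B, C = corners_pts
    op0, op1, op2 = _opening_list(spec)
    if spec.wall_kind == "straight":
        pieces = [
            WallPiece(Segment(op0.lo, C), None, 0),
            WallPiece(Segment(C, op2.lo), 0, None),
            WallPiece(Segment(op2.hi, B), None, 1),
            WallPiece(Segment(B, op1.lo), 1, None),
            WallPiece(Segment(op1.hi, A), None, 2),
            WallPiece(Segment(A, op0.hi), 2, None),
        ]
    else:
        f = spec.bezier_control_fraction

        def bez(a, b, corner):
            return Bezier(a, a + f * (corner - a), b + f * (corner - b), b)

        pieces = [
            WallPiece(bez(op0.lo, op2.lo, C)),
            WallPiece(bez(op2.hi, op1.lo, B)),
            WallPiece(bez(op1.hi, op0.hi, A)),
        ]
    return pieces, [C, B, A]


def _chain_points(spec: BifurcationSpec, corners_pts, n_bez: int = 256):
    """Dense CCW boundary polyline and the chain indices of region anchors."""
    pieces, cpts = _wall_chain(spec, corners_pts)
    op0, op1, op2 = _opening_list(spec)
    chain: list[complex] = [op0.hi, op0.lo]
    anchors: list[int] = []
    if spec.wall_kind == "straight":
        # pieces: lo->C, C->c2lo, [opening2], c2hi->B, B->c1lo, [opening1], ...
        seq = [(pieces[0], pieces[1]), (pieces[2], pieces[3]),
               (pieces[4], pieces[5])]
        ends = [op2, op1, op0]
        for (pa, pb), op in zip(seq, ends):
            chain.append(pa.curve.b)  # the corner
            anchors.append(len(chain) - 1)
            chain.append(pb.curve.b)
            if op is not op0:
                chain.append(op.hi)
    else:
        ends = [op2, op1, op0]
        for piece, op in zip(pieces, ends):
            t = np.linspace(0.0, 1.0, n_bez + 1)[1:]
            pts = piece.curve.point(t)
            mid_local = np.argmin(np.abs(t - 0.5))
            anchors.append(len(chain) + mid_local)
            chain.extend(pts.tolist())
            if op is not op0:
                chain.append(op.hi)
    return chain, anchors


def _boundary_polygon(spec: BifurcationSpec, corners_pts,
                      with_particle: bool = False) -> Polygon:
    chain, _ = _chain_points(spec, corners_pts)
    shell = [(p.real, p.imag) for p in chain]
    holes = None
    if with_particle and spec.particle is not None:
        x0, y0, r = spec.particle
        ring = Point(x0, y0).buffer(r, quad_segs=180).exterior
        holes = [list(ring.coords)[::-1]]
    return Polygon(shell, holes)


def build_bifurcation(spec: BifurcationSpec) -> BifurcationDomain:
    """Construct the flow domain for a validated bifurcation spec.

    Raises :class:`GeometryError` naming the violated predicates if the spec
    is inadmissible.
    """
    report = validate_spec(spec)
    if not report.ok:
        raise GeometryError(report.violations)

    corners_pts, _ = _straight_corners(spec)
    openings = _opening_list(spec)
    pieces, cpts = _wall_chain(spec, corners_pts)

    corners: list[Corner] = []
    if spec.wall_kind == "straight":
        for i, cp in enumerate(cpts):  # order C, B, A
            before = pieces[2 * i].curve
            after = pieces[2 * i + 1].curve
            d_in = (before.b - before.a) / abs(before.b - before.a)
            d_out = (after.b - after.a) / abs(after.b - after.a)
            corners.append(_corner_geometry(cp, d_in, d_out, openings))
    else:
        for cp in cpts:
            corners.append(Corner(cp, math.pi, False, None, 1.0))

    particle = None
    if spec.particle is not None:
        x0, y0, r = spec.particle
        particle = ParticleSpec(complex(x0, y0), r)

    polygon = _boundary_polygon(spec, corners_pts, with_particle=True)
    domain = BifurcationDomain(spec, pieces, openings, corners, particle,
                               polygon)
    _attach_regions(domain, corners_pts)
    return domain


def _attach_regions(domain: BifurcationDomain, corners_pts) -> None:
    """Split the fluid area into parent/child regions through the origin.

    Divider lines join the origin to the three corners (straight walls) or to
    the Bezier midpoints (curved walls); a particle is clipped out of every
    region it overlaps.
    """
    spec = domain.spec
    chain, anchors = _chain_points(spec, corners_pts)
    iC, iB, iA = anchors
    origin = (0.0, 0.0)

    def poly_from(points):
        return Polygon([origin] + [(p.real, p.imag) for p in points])

    n = len(chain)
    parent = poly_from(chain[iA:n] + chain[0:iC + 1])
    child2 = poly_from(chain[iC:iB + 1])
    child1 = poly_from(chain[iB:iA + 1])
    regions = [parent, child1, child2]
    if domain.particle is not None:
        c = domain.particle.center
        disc = Point(c.real, c.imag).buffer(domain.particle.radius,
                                            quad_segs=180)
        regions = [r.difference(disc) for r in regions]
    domain.region_anchors = [chain[iA], chain[iB], chain[iC]]
    domain.region_polygons = regions


def region_areas(domain: BifurcationDomain) -> tuple[float, float, float]:
    """Areas (A0, A1, A2) of the parent/child-1/child-2 regions.

    The three areas sum to the fluid area (particle excluded) to relative
    1e-6.
    """
    if not domain.region_polygons:
        raise ValueError("domain carries no region decomposition")
    a = tuple(r.area for r in domain.region_polygons)
    total = domain.fluid_area
    if abs(sum(a) - total) > 1e-6 * max(1.0, total):
        raise AssertionError("region areas fail to add up to the fluid area")
    return a


def rectangle_channel(width: float = 1.0, length: float = 4.0) -> BifurcationDomain:
    """A straight channel on [-length/2, length/2] x [-width/2, width/2].

    Used for the plane-Poiseuille oracle: the domain has two openings
    (index 0 at the left, forward flow +X) and no corners, so the solver
    basis is purely polynomial.
    """
    hl, hw = length / 2.0, width / 2.0
    openings = [
        Opening(0, complex(-hl, 0), 1.0 + 0j, width),
        Opening(1, complex(hl, 0), 1.0 + 0j, width),
    ]
    walls = [
        WallPiece(Segment(complex(-hl, -hw), complex(hl, -hw))),
        WallPiece(Segment(complex(hl, hw), complex(-hl, hw))),
    ]
    poly = Polygon([(-hl, hw), (-hl, -hw), (hl, -hw), (hl, hw)])
    return BifurcationDomain(None, walls, openings, [], None, poly)


# ---------------------------------------------------------------------------
# boundary sampling


def _clustered_params(n_uniform: int, cluster_start: bool, cluster_end: bool,
                      n_cluster: int, sigma: float) -> np.ndarray:
    """Parameter values in (0,1), exponentially clustered at flagged ends.

    The clustering law matches the lightning pole law with ~3 samples per
    pole: distances L * exp(-sigma'(sqrt(M) - sqrt(k))) with
    sigma' = sigma / sqrt(3).
    """
    ts = [(np.arange(n_uniform) + 0.5) / n_uniform]
    if n_cluster > 0:
        k = np.arange(1, n_cluster + 1)
        d = np.exp(-sigma / math.sqrt(3.0)
                   * (math.sqrt(n_cluster) - np.sqrt(k)))
        if cluster_start:
            ts.append(0.5 * d)
        if cluster_end:
            ts.append(1.0 - 0.5 * d)
    t = np.unique(np.concatenate(ts))
    return t[(t > 0) & (t < 1)]


def _piece_samples(piece: WallPiece, corners: list[Corner], *,
                   n_uniform: int, samples_per_pole: int,
                   poles_per_corner: int, sigma: float):
    curve = piece.curve
    def active(idx):
        return idx is not None and corners[idx].reentrant
    n_cluster = samples_per_pole * poles_per_corner
    if isinstance(curve, Bezier):
        # concentrate mildly around t=0.5 where curvature peaks
        u = np.linspace(-1.0, 1.0, n_uniform, endpoint=False) + 1.0 / n_uniform
        t = np.unique(np.concatenate([
            (np.arange(n_uniform) + 0.5) / n_uniform,
            0.5 + 0.5 * u**3,
        ]))
        t = t[(t > 0) & (t < 1)]
    else:
        t = _clustered_params(n_uniform, active(piece.cluster_start),
                              active(piece.cluster_end), n_cluster, sigma)
    pts = curve.point(t)
    tangents = curve.tangent(t)
    # midpoint-gap arc-length weights on the curve parameter
    edges = np.concatenate([[0.0], 0.5 * (t[1:] + t[:-1]), [1.0]])
    if isinstance(curve, Bezier):
        speed = np.abs(curve.derivative(t))
        w = speed * np.diff(edges)
    else:
        w = curve.length * np.diff(edges)
    return pts, w, tangents


def sample_boundary(domain: BifurcationDomain, *, poles_per_corner: int = 48,
                    sigma: float = 4.0, samples_per_pole: int = 3,
                    wall_uniform: int = 24, opening_points: int = 48,
                    particle_points: int = 300,
                    pressures=(0.0, 0.0, 0.0)) -> BoundarySampleSet:
    """Collocation points, quadrature weights and BC tags on the boundary.

    Wall samples cluster toward reentrant corners with the same exponential
    law as the lightning poles; openings carry Gauss-Legendre nodes; a
    particle circle is sampled uniformly in angle.
    """
    pts, wts, tans, tags, vals, axes, pid = [], [], [], [], [], [], []

    def push(p, w, tg, tag, val, ax, k):
        pts.append(np.asarray(p, complex))
        wts.append(np.asarray(w, float))
        tans.append(np.asarray(tg, complex))
        n = len(np.asarray(p))
        tags.append(np.full(n, tag, dtype=int))
        vals.append(np.full(n, val, dtype=float))
        axes.append(np.full(n, ax, dtype=complex))
        pid.append(np.full(n, k, dtype=int))

    for k, piece in enumerate(domain.walls):
        p, w, tg = _piece_samples(piece, domain.corners,
                                  n_uniform=wall_uniform,
                                  samples_per_pole=samples_per_pole,
                                  poles_per_corner=poles_per_corner,
                                  sigma=sigma)
        push(p, w, tg, WALL, np.nan, 0j, k)

    xg, wg = np.polynomial.legendre.leggauss(opening_points)
    for op in domain.openings:
        a, b = op.lo, op.hi
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        p = mid + half * xg
        w = np.abs(half) * wg
        tg = np.full(len(p), half / abs(half), dtype=complex)
        tag = OPENING_TAGS[op.index]
        push(p, w, tg, tag, pressures[op.index], op.axis, 100 + op.index)

    if domain.particle is not None:
        c, r = domain.particle.center, domain.particle.radius
        th = 2 * np.pi * (np.arange(particle_points) + 0.5) / particle_points
        p = c + r * np.exp(1j * th)
        w = np.full(particle_points, 2 * np.pi * r / particle_points)
        tg = -1j * np.exp(1j * th)  # clockwise traversal (fluid on the left)
        push(p, w, tg, PARTICLE, np.nan, 0j, 200)

    points = np.concatenate(pts)
    tangents = np.concatenate(tans)
    return BoundarySampleSet(
        points=points,
        weights=np.concatenate(wts),
        tangents=tangents,
        normals=-1j * tangents,
        bc_tag=np.concatenate(tags),
        bc_value=np.concatenate(vals),
        axis=np.concatenate(axes),
        piece_id=np.concatenate(pid),
    )
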