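"""Rational approximation basis for the Goursat functions.

Each Goursat function is expanded in a shared scalar basis

    r(z) = sum_k b_k p_k(z)  +  sum_j a_j / (z - z_j)  +  sum_j c_j (z - c)^-j,

where ``p_k`` is a polynomial basis orthogonalized on the boundary samples by
the Vandermonde-with-Arnoldi recurrence, the simple poles ``z_j`` are either
exponentially clustered at reentrant corners (lightning poles) or taken from
an AAA approximation of the Schwarz function of each curved wall, and the
Laurent block handles a circular hole.  For a hole the basis additionally
carries one *log pair*: a single real-coefficient pair of columns

    f += a log(z - c),    g += -conj(a) [(z - c) log(z - c) - (z - c)],

whose combined velocity field is single-valued around the hole (the 2D
stokeslet pair required by the logarithmic conjugation theorem).  The pair
couples f and g, so it is expressed directly in the assembled columns rather
than as independent coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import AAA

__all__ = [
    "RationalBasis",
    "SchwarzBoundaryData",
    "arnoldi_fit",
    "arnoldi_evaluate",
    "lightning_poles",
    "aaa_schwarz_poles",
    "build_basis",
    "evaluate_basis",
]


class BasisError(RuntimeError):
    pass


@dataclass(frozen=True)
class SchwarzBoundaryData:
    """Samples of one curved arc and the Schwarz values F(z) = conj(z)."""

    samples: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return np.conj(self.samples)


# ---------------------------------------------------------------------------
# Vandermonde with Arnoldi


def arnoldi_fit(Z: np.ndarray, degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Arnoldi orthogonalization of the monomial basis on sample points Z.

    Returns (H, Q): the (degree+1, degree) upper-Hessenberg recurrence and
    the orthonormal basis values on Z (columns 0..degree).
    """
    m = len(Z)
    H = np.zeros((degree + 1, degree), dtype=complex)
    Q = np.zeros((m, degree + 1), dtype=complex)
    Q[:, 0] = 1.0
    for k in range(degree):
        q = Z * Q[:, k]
        for j in range(k + 1):
            H[j, k] = np.vdot(Q[:, j], q) / m
            q = q - H[j, k] * Q[:, j]
        H[k + 1, k] = np.linalg.norm(q) / math.sqrt(m)
        if H[k + 1, k] == 0:
            raise BasisError("Arnoldi breakdown: sample set too small for "
                             f"polynomial degree {degree}")
        Q[:, k + 1] = q / H[k + 1, k]
    return H, Q


def arnoldi_evaluate(Z: np.ndarray, H: np.ndarray, order: int = 1):
    """Evaluate the Arnoldi polynomial basis and derivatives at points Z.

    Derivatives are obtained by differentiating the recurrence, not by
    finite differences.  Returns a list [W0, W1, ..., W_order] of
    (len(Z), degree+1) matrices.
    """
    Z = np.asarray(Z, dtype=complex).ravel()
    degree = H.shape[1]
    m = len(Z)
    W = [np.zeros((m, degree + 1), dtype=complex) for _ in range(order + 1)]
    W[0][:, 0] = 1.0
    for k in range(degree):
        for d in range(order, -1, -1):
            q = Z * W[d][:, k]
            if d > 0:
                q = q + d * W[d - 1][:, k]
            for j in range(k + 1):
                q = q - H[j, k] * W[d][:, j]
            W[d][:, k + 1] = q / H[k + 1, k]
    return W


# ---------------------------------------------------------------------------
# pole placement


def lightning_poles(corner: complex, bisector: complex, N: int,
                    sigma: float = 4.0, scale: float = 1.0) -> np.ndarray:
    """Exponentially clustered poles along the solid bisector of a corner.

    Pole k (k = 1..N) sits at distance ``scale * exp(-sigma (sqrt(N) -
    sqrt(k)))`` from the corner, so the farthest pole is at distance
    ``scale`` and spacing tightens root-exponentially toward the corner.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    k = np.arange(1, N + 1)
    d = scale * np.exp(-sigma * (math.sqrt(N) - np.sqrt(k)))
    return corner + (bisector / abs(bisector)) * d


def aaa_schwarz_poles(data: SchwarzBoundaryData, domain=None,
                      tol: float = 1e-8, max_terms: int = 120):
    """Poles of an AAA rational fit of the Schwarz function of one arc.

    Fits F(z) = conj(z) on the arc samples in barycentric form, checks the
    achieved error against ``tol`` (relative to the arc scale), and returns
    the poles lying strictly outside the fluid domain (spurious poles inside
    the domain are discarded).
    """
    z = np.asarray(data.samples, dtype=complex)
    if len(z) < 16:
        raise ValueError("need at least 16 samples on the arc")
    vals = data.values
    scale = max(np.max(np.abs(vals)), 1.0)
    with np.errstate(all="ignore"):
        r = AAA(z, vals, rtol=tol, max_terms=max_terms, clean_up=True)
        err = float(np.max(np.abs(r(z) - vals)))
    if err > 10 * tol * scale:
        raise BasisError("AAA failed to reach the requested tolerance: "
                         f"achieved {err:.3e} with max_terms={max_terms}")
    poles = np.asarray(r.poles(), dtype=complex)
    poles = poles[np.isfinite(poles)]
    if domain is not None and len(poles):
        inside = domain.contains(poles)
        poles = poles[~inside]
    return poles, err


# ---------------------------------------------------------------------------
# assembled basis


@dataclass
class LaurentBlock:
    center: complex
    degree: int
    scales: np.ndarray = field(default=None)  # per-order column scaling


@dataclass
class RationalBasis:
    """Scalar rational basis shared by the two Goursat functions.

    Column order of :meth:`evaluate`: polynomial (degree+1 columns), then
    poles, then Laurent blocks.  The log pair of each hole is exposed through
    :meth:`log_pair` because it couples f and g.
    """

    poly_degree: int
    hessenberg: np.ndarray
    poles: np.ndarray
    pole_scales: np.ndarray
    laurent_blocks: list[LaurentBlock]
    log_centers: list[complex]
    log_scales: list[float]
    boundary_points: np.ndarray

    @property
    def n_columns(self) -> int:
        return (self.poly_degree + 1 + len(self.poles)
                + sum(b.degree for b in self.laurent_blocks))

    @property
    def counts(self) -> dict:
        return {
            "n_poly": self.poly_degree + 1,
            "m_poles": len(self.poles),
            "p_holes": len(self.laurent_blocks),
            "q_laurent": max((b.degree for b in self.laurent_blocks),
                             default=0),
        }

    def evaluate(self, points, order: int = 1) -> list[np.ndarray]:
        """Values and derivatives of every scalar column at ``points``.

        Returns [B0, B1, ..., B_order], each of shape (npts, n_columns).
        """
        z = np.asarray(points, dtype=complex).ravel()
        W = arnoldi_evaluate(z, self.hessenberg, order=order)
        blocks = [[w] for w in W]  # per-order lists of column blocks
        if len(self.poles):
            dz = z[:, None] - self.poles[None, :]
            col = self.pole_scales[None, :] / dz
            blocks[0].append(col)
            fac = 1.0
            for d in range(1, order + 1):
                fac *= -d
                blocks[d].append(fac * self.pole_scales[None, :]
                                 / dz ** (d + 1))
        for blk in self.laurent_blocks:
            j = np.arange(1, blk.degree + 1)
            dz = z[:, None] - blk.center
            blocks[0].append(blk.scales[None, :] * dz ** (-j[None, :]))
            for d in range(1, order + 1):
                coef = (-1.0) ** d * np.ones_like(j, dtype=float)
                for t in range(d):
                    coef = coef * (j + t)
                blocks[d].append(blk.scales[None, :] * coef[None, :]
                                 * dz ** (-(j[None, :] + d)))
        return [np.concatenate(bs, axis=1) for bs in blocks]

    def log_pair(self, points, order: int = 1):
        """Columns of the hole log terms (one per Goursat function).

        Each hole carries four real unknowns: the *stokeslet pair*
        ``(a_r, a_i)`` -- ``f += a log(z-c)`` coupled with
        ``g += -conj(a) [(z-c) log(z-c) - (z-c)]`` so the pair's velocity is
        single-valued -- and the *rotlet* ``(d_r, d_i)`` with
        ``g += d log(z-c)``, whose velocity only involves ``g'`` and is
        single-valued on its own.  Returns a list over holes of dicts with
        keys ``f0, f1[, f2], g0, g1[, g2]``, each of shape (npts, 4).
        """
        z = np.asarray(points, dtype=complex).ravel()
        zero = np.zeros(len(z), dtype=complex)
        out = []
        for c, s in zip(self.log_centers, self.log_scales):
            dz = z - c
            lg = np.log(dz)
            h0 = dz * (lg - 1.0)
            cols = {
                "f0": s * np.stack([lg, 1j * lg, zero, zero], axis=1),
                "f1": s * np.stack([1 / dz, 1j / dz, zero, zero], axis=1),
                "g0": s * np.stack([-h0, 1j * h0, lg, 1j * lg], axis=1),
                "g1": s * np.stack([-lg, 1j * lg, 1 / dz, 1j / dz], axis=1),
            }
            if order >= 2:
                cols["f2"] = s * np.stack([-1 / dz**2, -1j / dz**2,
                                           zero, zero], axis=1)
                cols["g2"] = s * np.stack([-1 / dz, 1j / dz,
                                           -1 / dz**2, -1j / dz**2], axis=1)
            out.append(cols)
        return out

    @property
    def n_log_unknowns(self) -> int:
        return 4 * len(self.log_centers)


def build_basis(domain, samples, *, poly_degree: int = 24,
                poles_per_corner: int = 48, sigma: float = 4.0,
                laurent_degree: int = 20, aaa_tol: float = 1e-8,
                aaa_max_terms: int = 120) -> RationalBasis:
    """Assemble the rational basis for a sampled domain.

    Lightning poles are attached to every reentrant corner; curved (Bezier)
    walls contribute AAA poles of their Schwarz function; a particle hole
    contributes a Laurent block and the log pair about its centre.  Pole and
    Laurent columns are scaled to unit maximum modulus on the boundary
    samples.
    """
    from .geometry import Bezier  # local import to avoid cycle at load

    Z = samples.points
    poles = []
    for corner in domain.corners:
        if corner.reentrant:
            poles.append(lightning_poles(corner.point, corner.bisector,
                                         poles_per_corner, sigma,
                                         corner.pole_scale))
    for piece in domain.walls:
        if isinstance(piece.curve, Bezier):
            t = np.linspace(0.0, 1.0, 200)
            arc = SchwarzBoundaryData(piece.curve.point(t))
            p, _ = aaa_schwarz_poles(arc, domain, tol=aaa_tol,
                                     max_terms=aaa_max_terms)
            if len(p):
                poles.append(p)
    poles = (np.concatenate(poles) if poles
             else np.empty(0, dtype=complex))
    if len(poles):
        inside = domain.contains(poles)
        if inside.any():
            raise BasisError(f"{int(inside.sum())} poles fall inside the "
                             "fluid domain (misdirected corner bisector?)")
    pole_scales = (np.min(np.abs(Z[:, None] - poles[None, :]), axis=0)
                   if len(poles) else np.empty(0))

    H, _ = arnoldi_fit(Z, poly_degree)

    laurent_blocks, log_centers, log_scales = [], [], []
    if domain.particle is not None:
        c = domain.particle.center
        j = np.arange(1, laurent_degree + 1)
        rmin = np.min(np.abs(Z - c))
        laurent_blocks.append(LaurentBlock(c, laurent_degree, rmin ** j))
        log_centers.append(c)
        log_scales.append(1.0 / max(np.max(np.abs(np.log(Z - c))), 1.0))

    basis = RationalBasis(poly_degree, H, poles, pole_scales,
                          laurent_blocks, log_centers, log_scales, Z)

    n_real_unknowns = 4 * basis.n_columns + basis.n_log_unknowns
    if 2 * len(Z) < 2 * n_real_unknowns:
        raise BasisError(
            f"under-resolved boundary: {len(Z)} samples provide "
            f"{2 * len(Z)} rows for {n_real_unknowns} real unknowns")
    return basis


def evaluate_basis(basis: RationalBasis, points, order: int = 1):
    """Functional wrapper around :meth:`RationalBasis.evaluate`."""
    return basis.evaluate(points, order=order)
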