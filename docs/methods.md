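# Methods

`bifstokes` computes steady Stokes flow through a two-dimensional channel
bifurcation and reduces it to the 0D conductance description used by flow
network models. This note records the model, the numerical method, the
defaults, and the design choices made where more than one construction was
defensible.

## Physical model and scaling

The fluid is incompressible and inertialess: `mu lap(u) = grad p`,
`div u = 0`. All quantities are dimensionless: lengths on the parent channel
width `d`, velocities on `q/d` (with `q` the inlet flux), pressures on
`mu q / d^2`. The `DimensionalScales` type performs these conversions and
nothing else; the solver never sees dimensional numbers.

The geometry is a parent channel of unit width whose centreline runs along
the negative X axis, and two child channels of widths `D1, D2 <= 1` leaving
the origin at angles `+alpha` (upper) and `-beta` (lower) from the positive
X axis, each of centreline length `L` (default 2, long enough for the flow
to become fully developed at the openings while keeping the junction's
influence visible). Boundary conditions: no slip on walls (and on an
optional rigid circular particle), and at each opening a prescribed pressure
together with zero transverse velocity — jointly equivalent to fully
developed parabolic inflow/outflow. The inlet pressure is the gauge,
`P0 = 0`.

**Admissibility.** A spec is rejected when `alpha + beta < pi/2`. At unit
child widths the channels then overlap; at smaller widths they pinch a
small-angle solid sliver between the children. The sliver makes the corner
between the children approach a slit (fluid angle near 360 degrees), where
the clustered-pole basis loses accuracy root-exponentially slower — we
measured residual floors of 1e-3 to 0.2 there at any clustering rate — so
these geometries are excluded outright rather than solved badly. Further
predicates: wall-line intersections must exist (non-parallel), every corner
must project within centreline distance `L` of the origin on its adjacent
channel axes, the boundary polygon must be simple, and a particle must
clear the walls by more than 1e-3.

**Degenerate angles.** `alpha` or `beta` equal to 0 or pi/2 can make two
wall lines coincide (for example `beta = 0` at `D2 = 1` merges the parent
and child-2 lower walls). The "corner" is then flat: it is recorded at the
foot of the origin on the common line with interior angle pi, and receives
neither poles nor clustered samples.

## Goursat representation

The stream function of any 2D Stokes flow is biharmonic and can be written
`psi = Im[conj(z) f(z) + g(z)]` with `f, g` analytic in the fluid. The
fields follow from

    U - iV     = -conj(f(z)) + conj(z) f'(z) + g'(z)
    P - i Omega = 4 f'(z)

The conjugation placement in the velocity relation is forced by
`U = dpsi/dY`, `V = -dpsi/dX`: writing `psi = Im[conj(z) f + g]` and
applying the Wirtinger derivative `d/dz - d/dconj(z)` to `psi` gives exactly
the displayed relation, and the plane-Poiseuille pair `f = -z^2`,
`g = z + z^3/3` (unit-maximum parabolic profile on a width-1 slab)
reproduces `U = 1 - 4Y^2`, `P = -8X`, `Omega = 8Y` — this closed form is a
unit test.

## Rational basis

Both Goursat functions share one scalar basis:

* **Polynomial**, degree `n` (default 24), orthogonalized on the boundary
  samples by the Vandermonde-with-Arnoldi recurrence. Derivatives are
  evaluated by differentiating the recurrence, never by finite differences.
* **Lightning poles** at every reentrant corner: `N` poles (default 48)
  along the corner's solid-angle bisector at distances
  `scale * exp(-sigma (sqrt(N) - sqrt(k)))`, `k = 1..N`. Clustering rate
  `sigma = 4` and `scale` = distance from the corner to the nearest adjacent
  opening. Both follow the lightning-solver literature; scans over
  `sigma in [2.5, 4.5]` and scale multipliers in `[0.5, 1.5]` confirmed this
  pair minimizes the boundary residual for every admissible wedge angle
  (>= 90 degrees). Narrower wedges would want smaller `sigma`, which is one
  reason they are inadmissible (above).
* **AAA poles** for curved (Bezier) walls: the Schwarz function
  `F(z) = conj(z)` of each arc — which encodes the arc's shape and nothing
  else — is fitted by the AAA barycentric rational algorithm
  (`scipy.interpolate.AAA`, tolerance 1e-8, at most 120 support points);
  the fit's poles lying outside the fluid become basis poles. Spurious
  poles inside the domain are discarded by a point-in-polygon test. For a
  straight segment the Schwarz function is linear (no poles needed); for a
  circular arc it is `conj(c) + r^2/(z - c)`, and the recovery of the pole
  at the centre is an oracle test.
* **Hole terms** for an embedded particle: a Laurent block of degree `q`
  (default 20) about the particle centre in both `f` and `g`, plus the two
  log terms required in a multiply connected domain. These are (i) the
  *stokeslet pair* `f += a log(z - c)` coupled with
  `g += -conj(a) [(z - c) log(z - c) - (z - c)]` — the coupling coefficient
  `-conj(a)` is the unique choice making the pair's velocity single-valued
  around the hole, and it is built into the basis columns (2 real unknowns),
  not left to the solve; and (ii) the *rotlet* `g += d log(z - c)`, whose
  velocity involves only `g' = d/(z - c)` and is single-valued on its own.
  The rotlet is not in the Laurent span (Laurent terms in `g` differentiate
  to powers `-2` and below) and carries the torque on the particle; without
  it the no-slip condition on the cylinder cannot be met. Logs use the
  principal branch; all assembled rows depend only on branch-independent
  combinations, and the stream function's residual branch constant cancels
  in flux differences.

Pole and Laurent columns are rescaled to unit maximum modulus on the
boundary samples.

## Collocation and least squares

Walls are sampled with the same exponential law as the poles (three samples
per pole, clustered toward reentrant corners, reaching slightly inside the
innermost pole) plus a uniform complement; openings carry Gauss–Legendre
nodes (48 per opening by default); a particle circle is sampled uniformly.
Each sample contributes two real rows — `(U, V) = 0` on walls/particle,
(pressure, transverse velocity) at openings — scaled by the square root of
its arc-length quadrature weight, so the least-squares functional is a
boundary `L2` norm. Alternative weightings (unweighted, corner-distance)
were tested and are strictly worse.

The real unknowns are the stacked real/imaginary parts of the per-column
coefficients of `f` and `g` plus the four log unknowns per hole. The system
is column-equilibrated and solved by truncated-SVD least squares
(`scipy.linalg.lstsq`, `gelsd`, cutoff 1e-12 relative to the largest
singular value), which absorbs the Goursat gauge degeneracies without
explicit pinning. Several pressure vectors on one geometry share a single
assembly and factorization.

An optional `bc_mode="normal_stress"` replaces the pressure row by the full
normal-stress row `-P + 2 n.E.n` (requiring second derivatives of the
basis, also available analytically); for developed flow the two coincide,
which is verified on the rectangle channel.

**Accuracy.** On the straight reference bifurcation
(`D1=0.9, D2=0.8, alpha=pi/4, beta=pi/3`) the degree-24 / 48-pole basis
reaches a refined-sampling boundary residual of 1.1e-8 for the
equal-outlet-pressure flow (and ~4e-8 for the unit-pressure solves); this
is the basis' root-exponential floor, not a sampling artifact (degree 40
improves it only to 9e-9). Corners with 270-degree fluid angle floor near
5e-7 at 48 poles, and the particle case near 3e-6 — consistent with the
O(1e-7) regime the method is known for at these sizes. Conductances are
far more accurate than boundary residuals suggest, since flux errors
average the pointwise residual.

## 0D reduction

Fluxes are read off as stream-function differences between the two wall
endpoints of each opening (inlet positive inward, outlets positive outward)
and cross-checked by 64-point Gauss quadrature of `u . n`; mass
conservation `|Q - Q1 - Q2|` is enforced to max(1e-6, 10x the boundary
residual). Two solves with `P = (1, 0)` and `(0, 1)` give the conductance
tensor columns; the star triple `(G0, G1, G2)` follows in closed form from
the four outlet fluxes and the inlet-flux ratio, with a Levenberg–Marquardt
fit of the star model as fallback when the closed-form denominator nearly
cancels. The reconstruction of the tensor from the triple must match the
measured tensor (this enforces reciprocity `G12 = G21`, a nontrivial solver
check); the tolerance scales with the measured residual and is 1e-4 for
converged solves.

References: the Poiseuille triple `G~ = (1, D1^3, D2^3)/(12 L)` and its
network tensor; the area-preserved triple `G^` built from effective widths
`D^ = A/L`, where the region areas `A0, A1, A2` split the fluid by lines
joining the origin to the three corners (straight walls) or to the Bezier
midpoints at parameter 1/2 (curved walls), with any particle area clipped
out exactly (shapely polygon clipping; the circle is a 720-gon).

## Flow topology

All fixed-inlet-flux analyses superpose the two cached unit-pressure solves
(linearity; verified against direct re-solves to 1e-8). The reversal
threshold `dP* = P1 - P2` at which `Q1` vanishes under `Q = 1` follows in
closed form from the tensor (`(P1, P2) ~ (-G12, G11)` scaled to unit flux)
and is verified by a sign-change bracket. Streamlines integrate
`dz/dt = U + iV` with RK45 (rtol 1e-9), terminating on opening planes, on
near-wall approach (3e-4) or at stagnation (speed < 1e-7); the stream
function's drift along each path is recorded as a self-check. The forward
separatrix is anchored in flux coordinates — its level is
`psi(inlet bottom corner) + Q2`, so the inlet flux below it is exactly the
channel-2 share — rather than shot from near the corner, which is
ill-conditioned; its far end approaches a stagnation point on the
inter-child wall just off the sharp corner. For reversed channel-1 flow
the dividing level equals the upper-wall stream function and the curve is
traced backwards from the channel-2 opening, ending at the detachment
point on the upper wall; this anchoring is one reasonable reading of the
reversed-flow "separating streamline", which has no unique definition.

## Conductance surrogate

`generate_dataset` rejection-samples geometry parameters uniformly
(`straight`: `D1, D2 in [0.5, 1]`, `alpha, beta in [0, pi/2]` subject to
admissibility; `particle`: centre in `[-1, 1]^2`, radius in `(0, 0.3]`
subject to wall clearance, in the symmetric bifurcation) and solves each
row for the full triple. The default solver preset for dataset generation
(`FAST`: degree 16, 24 poles per corner) keeps per-row cost below 0.1 s at
conductance errors ~1e-6 absolute, far below the surrogate's own error;
rows that nevertheless warn about residuals are re-solved at reference
resolution.

Each conductance component gets its own `[in, 20, 20, 20, 1]`
rectified-linear network. Inputs are z-scored; the target is z-scored
during optimization (so the quasi-Newton gradient tolerance of 1e-9 is
meaningful at conductance scale ~1e-2) and the unscaling is folded into the
linear output layer, leaving a deterministic raw-scale forward pass that is
reimplemented in numpy for stored models. Training is full-batch L-BFGS
(scikit-learn `MLPRegressor`, no regularization, up to 5000 iterations);
fixed seeds give bitwise-identical weights on one platform. The validation
MSE is reported on the raw conductance scale. Exact MSE values are
seed-dependent; the suite asserts the order of magnitude (1e-5 for the
200-sample smoke set; the full 1000-sample run lands near 1e-7).

What the generator does *not* emulate: real microvascular networks have
non-Newtonian rheology, deformable particles, 3D lumens and longer
channels. Passing tests show the surrogate reproduces *this* model's
conductances, not in-vivo ones.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run single solves at the reference
discretizations (degree 24 / 48 poles; degree 80 + degree-20 Laurent for
the particle case), a 6x6 width grid and a 200-sample surrogate set at the
`FAST` preset. These sizes complete in about a minute total on one CPU;
the full 1000-sample surrogate experiment is a one-line change
(`generate_dataset("straight", 1000, seed)`) and lands in the same accuracy
envelope.

## Known limitations

* Single bifurcations only: no tree assembly, no haematocrit-dependent
  viscosity, no moving or multiple particles, no 3D.
* Geometries with inter-child wedge below 90 degrees are rejected (see
  Admissibility) even though some of them are geometrically constructible.
* The refined-sampling boundary residual at exactly degree 24 / 48 poles on
  the reference geometry is 1.1e-8 — the method's floor at that basis size;
  a handful more poles or degrees reach below 1e-8.
* The reversed-flow separatrix anchor is a convention (see Flow topology).
* `psi` is defined up to a constant (and, with a particle, up to a branch
  constant); only differences are meaningful.
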