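# Methods

## Model

Two rigid protein scaffolds are embedded in a fluid lipid membrane.  Each
scaffold is a patch of the quadric

    (x/rho_a)^2 + sign(rho_b) (y/rho_b)^2 + (z/rho_a)^2 = 1

cut by the elliptic cylinder (x/r_a)^2 + (y/r_b)^2 = 1 and referenced to its
apex.  Positive rho_b gives a convex (ellipsoidal) patch, negative rho_b a
saddle, |rho_b| = inf a cylindrical patch.  We keep the field's customary
labels c_a = 1/rho_a and c_b = 1/rho_b for the principal curvatures at the
center.  Note one subtlety we inherit deliberately: for rho_a != rho_b the
exact apex normal curvature along y of the quadric above is
sign(rho_b) rho_a/rho_b^2, not 1/rho_b, and the short-axis contact angle
arcsin(r_b/rho_b) is likewise nominal.  All computations use the quadric
itself; c_b = 1/rho_b is retained purely as the labeling convention for
parameter sweeps (so "c_b = 0.75 c_a" means rho_b = rho_a/0.75, etc.).

The membrane pays the Helfrich bending energy with modulus kappa
(default 20 k_B T) and zero spontaneous curvature,

    F = integral (kappa/2) J^2 dA,      J = c_1 + c_2 = 2H,

over the membrane outside the scaffold patches; the rigid scaffolds store no
elastic energy.  The Gaussian-curvature term is constant (Gauss-Bonnet with
fixed normals at the scaffold rims) and omitted identically.  An optional
lateral tension gamma adds gamma * (area - flat reference area); the
associated decay length is xi = sqrt(kappa/gamma).

Along each scaffold rim the membrane normal must coincide with the scaffold
surface normal (normal continuity; curvature continuity is not required —
the rim can exert bending moments).  The contact angle phi(azimuth) between
rim normal and center normal spans arcsin(r_a/rho_a) on the long axis to
(nominally) arcsin(r_b/rho_b) on the short axis.

A pair configuration is the center distance d, the in-plane angle phi
between each long axis and the connecting line (mirror-symmetric pair,
phi in [0, 90] deg), and the tilt theta of the center normal within the
plane containing the connecting line.  Tilt is signed: positive theta tips
the normal away from the partner.  This is where the minima lie — a convex
scaffold rides the partner's membrane depression, and the optimal tilt
decays roughly like 1/d.  Negative (toward) tilts are supported for the
asymmetric-orientation control and for sampling the orientational ensemble
across its minimum.  Asymmetric orientations (phi1 != phi2, theta1 !=
theta2) are supported as a control; production sweeps are mirror-symmetric.

## Discretization

The membrane is a triangle mesh.  The discrete bending energy is

    F = sum_v (kappa/2) |(L x)_v|^2 / A_v,

with L the cotangent (area-gradient) Laplacian, so (L x)_v is the
integrated mean-curvature vector and |(L x)_v|/A_v the total curvature J at
the vertex.  The energy uses barycentric vertex areas: unlike the
obtuse-safe mixed-Voronoi area (which the curvature *measurement* operator
offers as its default), the barycentric area is a smooth function of the
vertex positions, so the exact analytic gradient of F — assembled alongside
the energy — is smooth too.  Both area schemes partition the surface
exactly and converge on the analytic fixtures (sphere: F -> 8 pi kappa and
J -> 2/R; cylinder: J -> 1/rho; catenoid: F -> 0).

Boundary conditions.  Each scaffold contributes two fixed vertex rings
embedded on its analytic surface: the rim and a collar one edge-length
inside it.  The one-ring strip between them is rigid scaffold surface, and
the bending penalty of the hinge across the rim transmits the
normal-continuity condition to the free membrane to O(h).  The membrane
patch is a disc of radius L around the pair; the outer ring is *rigid at a
single shared height*: the mean (catenoid-like, zero-energy) far-field mode
floats freely, while the growing harmonic warp modes (r^m cos m phi) that a
closed vesicle cannot sustain are suppressed.  This matters: with a fully
free outer ring the minimizer absorbs scaffold boundary conditions into a
global membrane warp of enormous amplitude (we measured ring deflections of
+-185 length units on a domain of radius 300), producing spurious
kBT-scale "interactions"; with a fully clamped ring the monopole tail of a
cap pays a 1/log(L) artifact.  The rigid-ring condition avoids both and is
the flat-patch analogue of embedding the pair in a very large closed
vesicle.

Domain size.  Interaction energies are converged by L ~ 5 x d_ref with this
boundary treatment (checked at multiple L in the tests); larger domains add
poorly conditioned far-field modes without measurable benefit, so sweeps
use a common fixed L = max(5 d_ref, 25 r_a).  Using one L for a whole sweep
also makes the residual discretization error nearly constant in d, so it
cancels in the subtraction F_el(d) = F_min(d) - F_min(d_ref).

Meshing.  Vertex spacing grades geometrically from h at the rims (h ~
0.3-0.45 scaffold radii by profile) to ~0.22 r at distance r, with the
per-scaffold graded rings extended until they match the far-field ring
spacing (no resolution seams).  The mesh is a constrained Delaunay
triangulation of this point set with the collar interiors carved out;
midpoint subdivision with reprojection of ring vertices onto the analytic
surface provides refinement levels, and the inter-level energy difference
is the reported mesh error estimate.

## Minimization

Cold starts are seeded by the linearized (small-gradient) height solution
on the same mesh — one sparse solve of kappa L^T diag(1/A) L z = 0 with the
ring heights as data, regularized by a weak tension-like term
16 kappa / L^2 that pins the discrete harmonic modes the quadratic form
cannot see.  The nonlinear energy is then minimized by L-BFGS over the free
vertices in stages, preconditioned by the local length scale sqrt(A_v)
(without which the three-decade spread of edge lengths stalls descent).
Production stages move vertices vertically only: the relaxed surface is a
height field over the fixed in-plane layout, which is a consistent
discretization (the representable surfaces are the same graphs), is immune
to the tangential element collapse that plagues unregularized full-3D
relaxation, and converges to gradient norms ~1e-6 in seconds.  Optional
short full-3D stages (xyz_stages > 0) adapt the mesh tangentially, playing
the role of the facet-averaging regularization of classic surface-evolution
practice; the resulting discretization offset (a few percent of local
energies) cancels in interaction differences either way.  Warm starts
interpolate the previous solution's heights; sweeps chain them along d and
along orientation grids.  The procedure is deterministic; a seeded
vertex-jitter restart is available and off by default.

## Interaction energies

F_el(d) = F_min(d) - F_min(d_ref) with F_min the membrane energy minimized
over (phi, theta) at each d: a coarse grid scan, then sequential parabolic
line minimization in theta to ~0.05 deg (essential — the optimal tilt is
sub-degree at large d and the energy is steeply quadratic around it),
then parabolic refinement in phi.  Ties break toward smaller phi, then
smaller theta.  d_ref defaults to 20 r_a (the "infinite" separation);
locating an energy-well minimum does not depend on d_ref, and its
sensitivity can be probed by passing any other value.

Configuration validity.  Orientations whose scaffolds would overlap are
excluded as infinite-energy: the placement guard checks both the rim
projections along the connecting line (with a two-edge-length clearance)
and the true 3D surface-to-surface distance (tilted scaffolds can
approach in 3D while their projections stay apart).  In addition, tilts
with |theta| + (max contact angle) >= 85 deg are excluded: there the
membrane overhangs at the rim and the height-field discretization stops
being a valid surface model (and, numerically, starts producing
meaningless energies rather than the very large true ones).  Warm starts
between orientation evaluations are only taken from neighbors within
30 deg in phi and 20 deg in theta; interpolating a distant orientation's
shape can trap the descent in a spurious minimum.

The free energy integrates the Boltzmann weight of F_m over the
orientation ensemble, F(d) = -kT log ∫∫ exp(-F_m/kT) dtheta dphi (angles
in radians; the measure constant cancels in differences, which is all we
report).  Both angles are sampled adaptively around the energy minimum:
expanding steps until F_m exceeds the minimum by 4 k_B T, then a fixed
number of nodes (7/5 for theta, 9/5 for phi by profile) across the
detected window, monotone-cubic interpolation inside, and a quadratic,
forced-rising continuation matched at the window edges outside (the
excluded wings carry weight < e^-4; any smooth monotone extension changes
F by less than the grid error, which we verify by doubling the node
counts).  The phi integral runs over the effective potential
G(phi) = -kT log ∫ exp(-F_m(phi, theta)/kT) dtheta.  Adaptive phi
sampling (rather than fixed quadrature nodes) matters for strongly
elongated scaffolds, whose phi well can be a degree wide and sit at the
phi = 90 range boundary where fixed node sets have no support.
F_ent = F - F_el pointwise.  Only mirror-symmetric orientations enter the
ensemble, so F_ent is a documented lower bound on the full
orientational-entropy repulsion; membrane-undulation (Casimir) entropy is
out of scope.

Far-field power laws are least-squares slopes of log|F_el| vs log d over a
stated window ([5, 9.5] r_a by default; all points must share one sign).
With d_ref = 20 r_a the subtracted tail biases a true 1/d^4 slope by about
-0.08 and a true 1/d^2 slope by about -0.2 over this window — well inside
the fitting scatter, and quoted with the fit.

## Linearized cross-check

An independent finite-difference Monge-gauge solver (regular grid, 5-point
Laplacian squared, scaffold footprints imposed as Dirichlet patches,
clamped frame) provides the small-gradient limit.  It shares no code path
with the mesh engine beyond the scaffold surface formula and serves as the
shallow-regime oracle for the interaction curve.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| kappa | 20 k_B T | bending modulus |
| gamma | 0 | lateral tension (k_B T / length^2); xi = sqrt(kappa/gamma) |
| h | 0.3-0.45 r_a | mesh edge length at the rims (0.12 for sub-radius gap studies) |
| L | 5 x d_ref | membrane patch radius |
| d_ref | 20 r_a | reference separation standing in for infinity |
| theta window | 4 k_B T | sampled tilt range for the orientation ensemble |
| max_iter | 2400-6000 | descent budget per configuration (profile) |

## Study conditions

The shallow series uses circular footprints r_a = r_b = a with a/rho_a =
0.2, kappa = 20 k_B T, and c_b/c_a in {1, 0.75, 0, -0.75, -1}; the
elongated series fixes sqrt(r_a r_b) = 0.2 rho and varies r_a/r_b; the BAR
geometry is r_a = 6.5 nm, r_b = 1.5 nm, rho_a = 8.5 nm with c_b scanned
around 0.2 nm^-1.  The tension control uses r_a = 0.23 rho_a,
r_b = 0.175 rho_a, rho_b = rho_a and xi = 100 r_a.

## Tension decomposition

With lateral tension the total energy splits into the bending integral and
gamma times the excess area; interaction curves report both parts
(referenced to d_ref).  Two regimes are worth distinguishing.  At fixed
zero tilt the tension-mediated part of the interaction is *attractive*
and grows toward contact — the capillary flotation ("Cheerios") behavior
of same-sign deformations.  At the per-configuration optimal tilt the
tension part is repulsive and grows with gamma, while the curvature part
stays equal to the tensionless interaction whenever the decay length
xi = sqrt(kappa/gamma) is much larger than the scaffolds and their
separation (verified at xi = 100 x size to ~1e-4 k_B T; the repulsive
sign is resolvable at xi ~ 10 x size).

## BAR-geometry resolution limits

The BAR scaffold (aspect ratio ~4.3, contact angle ~50 deg on the long
axis, rim dimple ~3 nm deep) stresses the discretization hard.  The
*fixed-orientation* interaction is reliable at h ~ 0.85 nm because the
rim/collar/strip layout is identical for all distances, so the (large,
~5% of the ~300 k_B T self-energy) rim discretization error cancels in
F_el differences: the side-by-side pair binds by ~20 k_B T between
d = 10 and 20 nm at c_b = 0.05 nm^-1, deepening with resolution.
*Orientation-resolved* differences do not enjoy that cancellation: at
h ~ 0.85 nm the theta landscape scatters by tens of k_B T between
converged solves a degree apart (the hinge is multistable on coarse
meshes), so the ~1 k_B T orientational-entropy contribution at the BAR
optimum — small precisely because the orientation well is steep — lies
far below the desk-scale noise floor.  The entropy pipeline still runs
and reports its value, but only the elastic well depth is asserted
quantitatively at this geometry.

## Known limitations

* The gap between nearly touching scaffolds needs edge lengths well below
  the gap width; equilibrium distances below ~2.3 r_a are at the resolution
  limit of the default profiles (the overlap guard enforces a two-cell
  gap).
* The hinge realization of normal continuity is O(h); contact-angle
  sensitive quantities carry the mesh error bar from refinement levels.
* The entropic interaction is a lower bound (symmetric orientations only).
* Vertical-only relaxation presumes the membrane stays a graph over the
  built layout; for strongly tilted, strongly curved scaffolds (tilts
  beyond ~60 deg on the BAR geometry) the full-3D stages should be enabled
  and convergence watched.
* Single-scaffold self-energies depend on the global boundary treatment
  (free vs rigid vs clamped ring) at the fraction-of-kBT level; only
  energy *differences* between configurations with the same domain are
  physically meaningful outputs.
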