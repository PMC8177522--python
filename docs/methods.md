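# Methods

## Model and discretization

The package solves the quasi-static bioelectric forward problem: the
potential `u` in the head domain satisfies
`div(sigma grad u) = div j^p` with the no-flux condition
`<sigma grad u, n> = 0` on the scalp, where `sigma` is a symmetric
positive-definite conductivity tensor field given per mesh element and the
primary current of a dipole is `div j^p = q . grad delta_{x_dp}`. The library
is unit-agnostic — positions, conductivities and moments only need to be
mutually consistent; every bundled fixture and default uses SI units (m, S/m,
A·m, V, T).

Two fitted discretizations share one mesh/conductor data model:

- **CG-FEM**: P1 on tetrahedra (constant gradients, exact assembly) and Q1 on
  hexahedra (2×2×2 Gauss quadrature). One unknown per vertex.
- **DG-FEM (SIPG)**: the same elementwise polynomials without continuity;
  interior faces carry the consistency, symmetry and penalty terms. Averages
  are conductivity-weighted (harmonic/SWIP): with `delta = <n, sigma n>` on
  either side, weights `omega_- = delta_+/(delta_- + delta_+)` and penalty
  scale `gamma_F = 2 delta_- delta_+ / (delta_- + delta_+)`, so that skull
  faces with an 80-fold contrast are penalized on the scale of the weaker
  conductor. The effective penalty is `eta * gamma_F / h_F` with `h_F` the
  face diameter and `eta = 4` by default. Face quadrature assumes planar
  faces (exact for the voxel grids generated here). Natural boundary
  conditions add no boundary-face terms, so constants span the kernel and
  the matrix stays symmetric.

Both operators are singular positive-semidefinite with kernel dimension 1 on
a connected mesh. **Gauge**: no node is grounded; right-hand sides and
solutions are demeaned instead. This preserves the symmetry of `A` exactly,
which the transfer-matrix construction `A T^t = R^t` relies on, and makes all
sensor quantities reference-free (potential *differences* are invariant).

The sign convention is fixed once by the weak form
`int <sigma grad u, grad phi_i> = int j^p . grad phi_i = b_i`,
under which a dipole pointing at an electrode raises its potential; the
analytic-sphere comparison in the test suite pins this down.

## Source models

All models are linear in the moment `q` and, for the direct models, produce
sparse vectors whose support is bounded independently of mesh size.

- **Partial integration**: `b_i = q . grad phi_i(x_dp)` on the basis
  functions of the containing element.
- **St. Venant**: monopole loads on the vertex star of the mesh vertex
  closest to `x_dp`. The zeroth moment (0) and first moment (`q`) are imposed
  as exact equality constraints; second moments and a Tikhonov term
  `lambda ||a||^2` (`lambda = 1e-6`) are minimized in coordinates scaled by
  the star's mean edge length (KKT system). The equality constraints make
  `sum a_v = 0` and moment recovery hold to machine precision, which the
  conservation tests assert at 1e-8.
- **Full subtraction**: `u = u_inf + u_corr` with
  `u_inf = q.(y-x_dp) / (4 pi sigma_inf ||y-x_dp||^3)` and `sigma_inf` the
  isotropic part (mean eigenvalue) of the dipole element's tensor. The
  correction right-hand side is
  `b_i = -int sigma_corr grad(u_inf).grad(phi_i) - int_dOmega sigma_inf
  (grad(u_inf).n) phi_i` with `sigma_corr = sigma - sigma_inf I`; the volume
  term runs only over elements where `sigma_corr != 0` (none in a homogeneous
  conductor), order-4 Gauss quadrature. Storage is dense. Post-processing
  adds `u_inf` at the sensors and demeans; it can be disabled. A warning is
  issued when the conductivity varies next to the dipole element (the local
  homogeneity assumption), and an anisotropic dipole element is rejected.
- **Whitney** (tetrahedra only): the dipole current is expanded in the six
  lowest-order edge functions `w_ij = lambda_i grad lambda_j - lambda_j grad
  lambda_i` of the containing tet. Coefficients are the weighted-minimum-norm
  solution matching `int j^p_h = q` exactly, with barycentric position
  weights `lambda_i(x_dp) lambda_j(x_dp)` favoring edges near the dipole
  (one admissible variant of the position-based flavor). Because P1 test
  gradients are constant per element, this in-element variant produces the
  same load vector as partial integration — a consistency property the test
  suite checks — while the represented-moment identity is its discriminating
  invariant. Hexahedral meshes are rejected.

DG supports partial integration; the St. Venant/Whitney vertex constructions
and the subtraction weak form are CG-only here.

## Transfer matrices and MEG

`T = R A^{-1}` is computed row-wise (one gauge-fixed solve per sensor).
Applying `T` to a sparse right-hand side touches only the matching columns,
so per-dipole cost is O(nnz), independent of mesh size.

MEG splits `B = B^p + B^s`: the primary field is the analytic
`(mu0/4pi) q x r / ||r||^3` projection, the secondary field integrates
`-(mu0/4pi) sigma grad(u_h) x r / ||r||^3` per element with order-4 Gauss
rules (tensor rules on hexes; collapsed Gauss–Jacobi rules on tets so the
Duffy Jacobian is exact). A minimum coil distance of two element diameters
(default) keeps the smooth-but-peaked kernel resolvable at fixed order. The
secondary coupling matrix `S` yields the MEG transfer `T_meg = S A^{-1}`.
MEG is restricted to CG (a straight `sigma grad u_h` is not adequate for DG),
and the subtraction model requires an explicit acknowledgement flag because
its solution omits the singularity contribution's field.

## Localization

Dipole elements are found by a k-d tree over element centers (nearest-center
seed) followed by edge-hopping: test the point against each face plane
(signed distance against the face center/outer normal, tolerance 1e-12
relative to the element diameter), hop through the first face whose test is
positive, report OUTSIDE on a separating boundary face, FOUND when no face
separates (verified by the containment test: barycentric for tets, damped
trilinear Newton for hexes, tolerance 1e-10). Convexity is only needed along
the walk; a visited set bounds the walk by the element count and any STUCK
walk falls back to the O(n) linear search, whose first-hit-in-storage-order
rule also resolves points exactly on shared faces.

## Analytic references

`sphere_eeg` evaluates the Legendre series for a dipole in concentric
isotropic shells: the dipole frame is rotated so the dipole sits on the
z-axis, the moment splits into radial and tangential parts, and per degree
`n` a small linear system couples the per-shell radial coefficients
(`A r^n + B r^{-(n+1)}`, plus the `u_inf` multipole source term in the
innermost region) through continuity of `u` and `sigma du/dr` and the outer
no-flux condition. Radii are scaled by the outer radius for conditioning;
truncation at relative increment 1e-12 or degree 200 (configurable). The
multipole source coefficients are independently anchored by an exact
comparison with the closed-form `u_inf` in the test suite, and the homogeneous
central-dipole limit reproduces `u(R, theta) = 3 q cos(theta)/(4 pi sigma
R^2)` analytically. `sarvas_meg` implements the closed-form exterior field of
a dipole in a spherically symmetric conductor (zero for radial dipoles,
conductivity-independent). RDM and lnMAG are the comparison metrics.

## Solver

The linear solves use conjugate gradients on the demeaned system with a
preconditioner contract (any symmetric positive operator):

- `direct` — sparse LU of a grounded copy `A + alpha e0 e0^T`; CG then
  converges in a couple of iterations and repeated right-hand sides amortize
  the factorization. Default below 20k unknowns (3D LU fill makes it
  uneconomical beyond that: factoring a 55k Q1 system took ~80 s where
  Jacobi-CG needs ~1 s).
- `jacobi` — inverse diagonal; default for large systems (the 420k-unknown
  2 mm sphere solves in ~4 s).

Right-hand sides are checked for Neumann compatibility
(`|sum b| <= 1e-6 ||b||_1`), demeaned before and after the solve, and the
relative residual is verified against the tolerance after CG returns. The
assembly layer converges two orders below the advertised tolerance (default
1e-8): a residual tolerance is not an error tolerance under an 80-fold
conductivity contrast, and this margin is what lets the direct and
transfer-matrix routes agree within the advertised tolerance.

## Fixtures and what the tests show

The generators produce voxelized concentric-shell conductors (default three
shells, radii 0.092/0.086/0.080 m, conductivities 0.33/0.0042/0.33 S/m — a
standard skin/skull/brain configuration), conforming 6-tet (Kuhn)
subdivisions, golden-angle electrode caps on the upper hemisphere, Fibonacci
magnetometer shells with radial directions, and seeded Gaussian-noise
measurements calibrated to a requested SNR. All generators are pure functions
of their arguments and seeds.

Study sizes were chosen so each study answers its question at desk scale:
convergence ladders at 8/4/2 mm voxels, transfer equivalence and MEG at 4 mm,
cross-model agreement on the 2 mm (2.4M-element) tetrahedral sphere, scans
with 500 source locations, 32 sensors, 1 nA·m moments, 20 dB SNR with 100
replicates.

What passing these studies shows — and does not show: the voxelized sphere
exercises high contrast, eccentric sources, both element kinds and every
source model, but its geometry error is staircase-like and its conductivities
are piecewise-constant isotropic. Results do not certify accuracy on
realistic segmented head models (tissue anisotropy, thin CSF channels,
non-convex cortex), where only the localization fallback and the DG
formulation address the additional difficulties qualitatively.

## Known limitations

- Unfitted/level-set discretizations, mixed FEM, localized/projected
  subtraction variants, and DG-flux-based MEG are out of scope.
- DG source support is partial integration only; MEG is CG-only.
- At coarse resolution the SIPG and CG solutions genuinely differ on the
  high-contrast three-shell model (RDM ~0.1 at 4 mm with `eta = 4`); they
  agree on resolved homogeneous conductors and approach each other as `eta`
  grows — both verified in the suite. Neither is privileged as ground truth;
  the analytic series is.
- Hex face integrals assume planar faces (exact for voxel grids); strongly
  warped hexahedra are untested.
- The MSH reader supports ASCII v2.2 with volume elements only.
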