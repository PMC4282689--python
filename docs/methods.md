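# Methods

This note records the models behind `tendonfe`, the parameters that matter,
the numerical choices, and what the tests do and do not demonstrate.

## Finite-element core

Small-strain linear elasticity on 20-node serendipity hexahedra.  Voigt
order is `(11, 22, 33, 12, 13, 23)` with engineering shear strains
(`γ = 2ε_ij`); all 6×6 material matrices are written for this convention.
Node ordering (8 corners, 12 midside nodes) is tabulated in
`tendonfe/elements.py` and coincides with the common quadratic-hexahedron
conventions, so meshes export directly to legacy VTK.

Integration: the 2×2×2 reduced rule is the package default because the
microstructure reference model is a reduced-integration quadratic
formulation.  A single reduced-integration element has 12 zero-energy
modes — 6 rigid plus 6 hourglass (60 dofs minus 8 points × 6 constraints) —
and no hourglass stabilisation is implemented, so the production pipelines
(homogenisation, repair model) explicitly request the rank-sufficient
3×3×3 rule.  The homogenisation load cases are displacement-controlled on
the whole boundary, so either rule yields the same averaged response to
solver precision on the validation case.

Solver: direct sparse LU (`scipy.sparse.linalg.splu`/`spsolve`).  The
fibril/matrix contrast reaches 1,700:1; unpreconditioned iterative methods
degrade badly there while the direct factorisation handles every case in
this package (≤ ~10^5 dofs) in seconds.  A contrast above 10^5 (for
example a 0.1 MPa matrix against a 1,700 MPa fibril) triggers a warning:
that regime defeated the original microstructure analysis as well and is
outside the validated envelope.  Relative residuals above 10^-6 raise an
error carrying a 1-norm condition estimate.

Quadrature accuracy: for affine elements (constant Jacobian) the 3×3×3
rule integrates the stiffness integrand exactly; for curved or non-affine
elements the integrand is rational and the rule carries an inherent small
defect (~2×10^-5 relative on a mildly distorted element, measured against
a converged 6×6×6 reference).  Unit-cell interface elements are curved by
construction; the mesh-refinement check below bounds the consequence.

Units: the solver is unit-agnostic.  The repository standard is MPa-mm-N
at the macro scale; the unit cell is nondimensionalised by its edge length
(`d + s`), exploiting the scale invariance of linear elasticity, with
moduli still in MPa.

## Unit cell

Square-packed cylindrical fibrils: diameter `d = 100` nm, surface gap
`s = 14` nm, analytic volume fraction `π d² / 4(d+s)² = 0.60434`.  The
cross-section is meshed with a butterfly (O-grid) pattern — square core,
fibril ring layers to the circular interface, matrix ring layers to the
cell boundary — and extruded axially (2 layers over one cell edge; the
strain-controlled load cases produce axially uniform fields, so axial
resolution is immaterial).  Midside nodes of interface edges are snapped
onto the circle, so the realised volume fraction matches the analytic
value to ~10^-5 at the reference density (456 elements, the same order as
the reference microstructure mesh of 880).  The fibril-matrix bond is a
merged-node tie: under small strains, a no-slip no-separation contact is
mechanically identical to a shared interface.  `fibril_count_per_edge`
tiles the pattern for edge-effect studies.

Refinement: scaling every density control by 1.5 changes each of the nine
homogenised constants by < 0.03% (asserted at 2% in the suite), so the
reference density is comfortably converged for the quantities reported.

## Homogenisation

Strain-controlled: six canonical unit macro strains (three tensions, three
engineering shears, magnitude 10^-3 — immaterial in a linear model and
asserted so).  Two boundary-condition constructions are implemented:

* **KUBC** (affine displacements `u = ε̄·x` on every boundary node):
  simplest, exact for a homogeneous cell, used for the equal-phase
  validation (recovers 1,700 MPa and G = E/2(1+ν) = 653.8461538 MPa to
  solver precision).  KUBC is a stiffness upper bound, and for this
  geometry a severe one: the fibril sits 7 nm from the cell boundary, and
  the affine boundary drags it through that thin matrix skin.  At
  `Em = 10` MPa KUBC yields `E1 ≈ 299` MPa — an artefact of the boundary
  condition, not of the composite.
* **Periodic** (node-paired fluctuations, master-slave elimination on the
  geometrically periodic mesh, corner pinned): the default for production
  constants.  At `Em = 10` MPa it gives `E1 = 50.1` MPa and
  `ν13 = 0.0146`, reproducing the strong transverse softening the
  composite actually has.

The volume-averaged strain of every case is asserted equal to the applied
macro strain (average-strain theorem) to 10^-8; the averaged stress
vectors divided by the magnitude form `C̄`, symmetrised (asymmetry is
reported and is ~10^-14 relative).  Engineering constants come from
`S̄ = C̄⁻¹`; the transverse-isotropy pairs (E1/E2, G13/G23, ν13/ν23) are
averaged and the pre-averaging asymmetry reported (the 8-fold symmetric
mesh keeps it at rounding level).  A transverse-isotropy shortcut solves
4 cases and fills the other two by the 1↔2 axis swap; it is asserted to
match the 6-case run to 10^-6.  Constants are printed to 10 significant
figures: an orthotropic description at lower precision visibly perturbs
the repair-model response.

With equal phase Poisson ratios the exact axial modulus of an aligned
composite equals the Voigt mean, so `E3` sits on the upper Voigt-Reuss
bound by construction; the bound checks in the suite therefore carry a
10^-6 relative numerical allowance.

## Rule of mixtures and linear limits

`E_CT = Em·Ef/((1−Vf)·Ef + Vf·Em)`, inverted as
`Em = E_CT(1−Vf)Ef/(Ef − Vf·E_CT)`.  Applied to the printed group means,
the closed form gives `Em = 0.10205` MPa (proximal, `Ef = 3,000`) and
`0.0414` MPa (distal, `Ef = 200`); the corresponding published values
(0.1021, 0.0416) were evidently computed from unrounded intermediate
means, so agreement is asserted at printed precision only.

Linear-limit scaling: peak permissible stress = `E × 55/450` (MPa), from
the literature anchor of a 450 MPa tendon staying linear to 55 MPa.  The
composite peak stress combines phase limits as
`(1−Vf)·limit(Ef) + Vf·limit(Em)`.  **Note the weighting**: the fibril
term carries `1−Vf`, the matrix term `Vf`.  This is the convention that
reproduces the published series 156/90/84/83 MPa for
`Em = 1000/100/10/1` at `Ef = 1700`, `Vf = 0.6` under round-half-away
integer rounding; the familiar fibre-fraction weighting gives
174/132/126/125 instead.  Both the choice and its motivation are
deliberately prominent here because the quantity is convention-sensitive.

## Kessler repair model

Quarter-symmetry block `[0, 3.25] × [0, 1.75] × [0, 10]` mm (full
cross-section 6.5 × 3.5 mm), structured 10×6×20 hex20 mesh
(1,200 elements, the same order as the reference repair mesh), symmetry
planes at `x = 0` and `y = 0`, far face fixed axially.  The tendon is
isotropic (reference fit: E = 200 MPa, ν = 0.4) or orthotropic with the
homogenised constants (axis 3 → z).  The suture is a 1D elastic rod
(E = 1,000 MPa, ν = 0.4, diameter 0.2 mm): a shaft from the cut face to
the anchor at 5 mm (half the 1 cm repair length) at
(half-width/3, mid-quarter-thickness), then a transverse anchor segment to
the symmetry plane.

Couplings, in order of the modelling decisions they encode:

* The shaft is a pure axial truss; a 0.2 mm polypropylene rod's bending
  stiffness (EI ≈ 1000 × π×0.1⁴/4 ≈ 0.08 N·mm²) is negligible against
  every other stiffness in the model.
* Anchor segments are isotropic ties `factor × EA/L` (default factor 10):
  a taut grasping loop is transversely stiff through its tension — a
  mechanism a linear axial rod cannot represent — and without it the shaft
  tension cannot turn the corner into tissue bearing.  The factor is an
  order above the suture's own axial stiffness (so the rigid-tendon limit
  reduces to the free shaft stretch within a few percent) but far from
  rigid (a rigid footprint would act as a punch and concentrate bearing at
  its edges).
* Rod-tissue tie: penalty springs at 3-point Gauss stations along each
  segment (line-load bearing, not point springs), stiffness 10^3 N/mm per
  mm of rod normal to the rod axis and 10^-4 of that along it.  The
  published friction coefficient 0.005 is recorded in the spec but not
  used as a Coulomb law: at that value sliding is effectively free, and
  the tiny tangential penalty emulates it while keeping the model linear.
  The tangential fraction is deliberately far below the naive 10^-2: a
  shear-lag estimate (`√(EA·k_t)` against `EA/L = 6.3` N/mm) shows
  anything larger re-anchors the shaft along its length and corrupts the
  free-sliding behaviour the friction value implies.

Loading: an axial force on the rod node in the cut face, standing in for
the mirror half pulling the suture across the laceration.  The model is
linear, so one unit solve serves every increment; the force-displacement
curve is exactly linear and its slope is the repair stiffness.  The gap
between the stumps is the mean axial displacement of the cut-face tendon
nodes **relative to the suture strand crossing that face** (the symmetric
frame), i.e. the separation contributed per repair half; gap control
scales the unit load to the target (0.5 mm reproduces the published
gap condition; the implied suture load is ~3 N).

Stress-region metrics operate on element-centroid Von Mises values of the
tendon only.  The high-stress region is the set of elements at or above
50% of the peak; its extents are exceedance-weighted RMS widths
(`√(12·Var)` of member centroids, weights `vm − 0.5·peak`), which coincide
with bounding-box extents for uniform regions and a 2:1 synthetic Gaussian
bump (within 1%) but remain smooth on the 0.3-0.5 mm macro mesh, where
bounding boxes jump by whole elements.  The shielded-zone statistic
averages the 1 mm slab at the cut face (excluding a 0.5 mm radius around
the shaft) against the model mean.  With the homogenised materials the
aspect ratio rises monotonically (~1 → ~5) as the matrix softens from
1,000 to 1 MPa, and the shielded slab stays far below the model mean
throughout — the two qualitative findings this model exists to reproduce.
Peak values (2-4 MPa at the 0.5 mm gap) are mesh- and coupling-dependent
and are only checked for order of magnitude against the published
3.56 MPa.

## Synthetic laboratory data

Transverse tensile groups: strain from the 2.5 mm gauge, stress from the
nominal 5 × 2 mm cross-section with 2% calliper jitter; a C1 cubic toe
(default extent 5% strain) blending into a linear region with the group's
true modulus (lognormal between-sample scatter, default CV 25%, chosen to
land the n = 12 group standard deviation in the order of the reported
±0.08 MPa — the split between biological and measurement variance is not
identifiable from the published dispersions); additive Gaussian stress
noise (0.002 MPa); a parabolic roll-off beyond the configured linearity
limit (0.16 / 0.10 MPa — configured, not emergent).  Strain rate in the
1-10 %/s window only labels a sample: transversely the modulus was found
rate-independent there.  All generators are deterministic in
(seed, sample index) and emit their spec in the CSV header.

Modulus fitting scans sliding windows (≥ 30% of the pre-departure strain
range, three window lengths, 25 starts), scores by coefficient of
determination, and returns the best window's least-squares slope.  On
noise-free toe+linear curves it recovers the true slope to ~10^-4
relative; under the full noise model the window selection carries a small
(~0.1%) upward bias, well inside the Monte-Carlo standard error of the
recovery checks (100 replicate groups, asserted within 2 SE).

Half-Kessler curves: toe take-up plus linear repair stretch, measured
through a machine compliance `c` (displacement `d = d_repair + c·F`),
recorded from a 0.1 N pretension offset.  `compliance_correct` subtracts
`c·F` pointwise; a constructed round trip recovers the repair-only curve
to 10^-12.

What the synthetic data do *not* emulate: viscoelastic rate dependence,
freezing artefacts, grip slippage, and any real biological covariance
structure.  Passing recovery tests shows the reduction pipeline is
unbiased at the configured noise level, not that the instrument model is
faithful.

## Known limitations

* Linear elasticity only: no viscoelasticity, no large-deformation
  contact, no stick-slip; the published maximum-convergable-load sequence
  (an artefact of contact-element distortion) has no analogue here.
* The suture knot, loop geometry, and pull-through failure are outside the
  model; the anchor is a load-transfer footprint.
* KUBC constants for high-contrast cells are boundary-artefact-dominated
  (kept for validation and bounding); use the periodic constants.
* Poisson's ratio is capped well below the >0.8 apparent values reported
  for tendon; with ν = 0.3/0.4 the tissue is compressible in-plane, which
  mainly scales, not reshapes, the stress field.
* Exact published engineering-constant columns for unequal phases are not
  reproduced digit-for-digit: they depend on the original mesh and contact
  treatment, which are not recoverable; the suite instead asserts bound
  containment, transverse isotropy, monotonicity, and the anisotropy
  indicators.
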