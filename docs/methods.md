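# Methods

## Model

The brachial plexus of a human neonate is idealised as a planar,
single-material, linear-elastic structure under plane stress with unit
thickness (1 mm): the spinal cord is a vertical rectangular strip
(cranial = +y), each root C5–T1 is a straight strip of width equal to
its measured cranial-caudal diameter leaving the cord's lateral surface
at a configurable angle (measured against the caudal cord direction:
90° is perpendicular, < 90° descends), and the three trunks are strips
that continue the roots distally. Vertebral bodies, foramina,
connective tissue, and everything distal to the trunks are outside the
model. Loading is a uniform pressure on each distal trunk face acting
along the trunk axis, emulating caudal traction on the plexus with the
neck aligned. The analysis is static, small-strain and geometrically
linear; rate dependence enters only through the choice of modulus and
rupture load per loading-rate case.

### Geometry construction

Root *paths* (centrelines) carry the anatomical lengths — the sums of
the measured spinal-to-DRG, DRG-to-foramen and foramen-to-trunk
segments (30.5, 31.0, 33.5, 20.0 and 13.5 mm for C5..T1). Trunk path
lengths are the cord-to-distal-trunk totals minus those sums (upper
10.9 mm, middle 4.8 mm, lower 10.8 mm measured along C8), so the
reported path totals (41.4, 38.3, 30.8 mm) hold exactly by
construction.

Where a strip meets the cord it is cut by the cord surface (a mitre:
the junction face has length d/sin θ). For a two-root trunk the member
roots' inner lateral edges intersect at a point X; the trunk's proximal
face is the straight segment through X perpendicular to the trunk axis,
truncated by the roots' outer lateral edges. The member strips
therefore tile the trunk face exactly, which makes the downstream mesh
conforming with no gap or overlap, and puts the drawn trunk width
within 0.2% of the width implied by summing the member cross-sections.
The cost of this choice is that the *drawn* strip length (to the merge
face) can differ from the anatomical path length — for the bundled
anatomy the lower roots are drawn longer than their paths — and that no
root can carry less than the full applied pressure axially (see
"Junction stress sampling"). The trunk axis defaults to the bisector of
the member directions; it can be fixed per trunk in the configuration,
and fixed axes do **not** rotate when root angles are perturbed, which
is what couples angle variation to the junction stresses.

Feasibility is checked constructively (junction faces inside the cord
and pairwise disjoint, merges in front of the cord, no strip overlaps,
single connected domain via a buffered union); violations raise a
geometry-infeasible error naming the offending pair.

### Reconstructed parameters

The source anatomy records diameters and segment lengths but shows the
root angles, cord dimensions and attachment spacing only graphically.
These are therefore **reconstructed**: required configuration with
bundled defaults, calibrated once so that (a) the path totals hold
exactly (true for any angles, by construction) and (b) the baseline
quasistatic C5 junction stress approximates the reference 0.246 MPa
while the upper roots carry more stress than the lower ones. The
calibration explored root angles, attachment spacings, cord size, trunk
axes and the guided-support extent at the reference mesh size; the
chosen values live in `data/default_config.yaml` and are flagged there
as reconstructions, not measurements. With them the baseline
quasistatic profile is C5 0.258, C6 0.269, C7 0.264, C8 0.253, T1
0.252 MPa (dynamic case: exactly 0.653/0.332 times these).

Two properties of the reference results are *not* recoverable from
printed information and are knowingly not reproduced: the wide spread
of the reference per-root stresses (0.171–0.250 MPa) and the large
(tens of percent) responses to ±3°/±6° angle changes. Both hinge on
unprinted sketch and mesh details; in this reconstruction the five
junction values span only ~6% and the sweep responses are a few
percent. The clinically meaningful ordering — C5 and C6 above C8 and
T1 — does hold and is asserted in the tests.

## Load partition

Root cross-sections are ellipses A = (π/4)·d_cc·d_t; trunk areas are
member sums (tissue cross-section conserved as roots merge); the total
applied force is 5× the single-root rupture load; shares are
area-proportional (composite theory with equal modulus), so every trunk
sees the same distal pressure p = 5·F_fail/ΣA. The tabulated pressures
(0.332, 0.653 MPa) are used as the authoritative applied values; the
recomputed values agree within 0.2% (the dynamic case arithmetic gives
0.6523 vs the tabulated 0.653).

## Mesh

Each region is a four-sided patch meshed by transfinite interpolation:
all-quad, deterministic, bit-reproducible, with node numbering
lexicographic by region then grid index. Conformity at interfaces is by
construction (shared face-node coordinate arrays). Cross divisions per
root: max(2, ⌈longest face / h_max⌉); axial divisions honour h_max. At
the default bounds (h_max = 2 mm, h_min = 0.2 mm) the baseline mesh has
302 elements — the same order as the 212-element reference model.
Element quality (positive Jacobians at all integration points, edge
lengths within ±30% of the bounds, ≥ 90% quads) is checked by
`check_mesh_quality` and the test suite. Triangular (constant-strain)
elements are supported by the solver for junction wedges but the
current patch layout needs none.

## Solver numerics

* Elements: isoparametric bilinear quads, full 2×2 Gauss integration by
  default. The reference model used reduced-integration elements;
  reduced single-point integration with γ-mode (stiffness) hourglass
  control (coefficient 0.01·E·t·A·(bᵀb)) is available as
  `scheme="reduced_1pt"`. Full integration was preferred for the
  default because it has no tunable stabilisation parameter and its
  three-zero-eigenvalue spectrum is directly testable; the two schemes
  differ by well under 1% on the study quantities.
* Constraints: prescribed displacement components are eliminated;
  skew "guided" constraints n·u = 0 are enforced with Lagrange
  multipliers (sparse KKT system). A node may not be both prescribed
  and guided.
* Loads: consistent nodal forces from uniform edge tractions
  (½·p·t·ℓ per end node).
* Linear solve: deterministic sparse direct factorisation
  (SuperLU via scipy); singular systems raise a rank-deficiency error.
  Every solve records the global equilibrium residual
  ‖Σ reactions + Σ applied‖/Σ|f|, asserted < 1e-8 throughout.
* Stress recovery: σ = D B u at the 2×2 Gauss points and at the element
  centroid; von Mises under plane stress. Negative round-off under the
  square root is clamped at zero.

## Boundary conditions

The cord midline node column is encastré. The reference model's
"XYSMM" conditions on "the superior and inferior portions of the five
nerves" are not a standard keyword; they are interpreted as
symmetry-type guided supports — the displacement component transverse
to the local nerve axis is fixed, the axial component free — applied to
the distal *portion* (default fraction 0.5, configurable) of the
superior lateral edge of C5 and the inferior lateral edge of T1. This
keeps the plexus stretching in its plane without over-anchoring the
junction regions.

## Junction stress sampling

The quantity reported per root is the maximum von Mises stress where
the root joins the cord. Three samplings are implemented
(`measure` in `max_junction_stress`):

* `nodal_avg` (default): largest contour-style nodal value over the
  interface nodes — the mean centroid von Mises of the elements
  incident to the node. This is what a CAE stress-contour display
  reports at the junction, which is how the reference values were read,
  and it blends the root-side and cord-side stress states.
* `centroid`: largest element-centroid value among elements adjacent to
  the interface.
* `max_gp`: largest Gauss-point value among those elements.

The element-max variants sit near the applied pressure for every root:
with exactly tiling trunk faces each root carries the full pressure
axially, so the first element row inside a root cannot fall much below
p = 0.332 MPa. Only the averaged measure reproduces the magnitude of
the reference junction values; this is recorded as a deliberate design
choice.

Because the re-entrant junction corners are stress singularities of the
elasticity problem, the *maximum* junction value grows under uniform
refinement and is meaningful only at a stated discretisation; all
reported junction stresses belong to the 2 mm / 0.2 mm reference mesh.
Mesh convergence is demonstrated on quantities that do converge:
distal displacements (< 0.1% between the reference mesh and one
refinement on the bar fixture) and the away-from-corner junction stress
on the clamped bar (< 2% for the same step).

## Verification fixtures (synthetic data)

No external data exist; every solver property is checked against
analytic oracles generated in `plexusfem.fixtures`:

* **Uniform bar** (clamped end, end pressure): for ν = 0 the exact
  solution (σ_xx = p, u_end = pL/E) lies in the bilinear element space
  and the solver reproduces it to 1e-8 relative; with ν = 0.4 the
  clamped end makes the problem non-trivial and the fixture drives the
  mesh-convergence checks. The bar dimensions (41.4 × 3 mm, case-1
  material) make its 9.29 mm end displacement directly comparable to
  the plexus upper trunk's 7.7 mm — the difference is the geometry
  (cord compliance, merges, oblique pulls).
* **Patch test**: five distorted quads in a unit square under an
  imposed random linear displacement field; interior displacements and
  the constant stress must be exact to 1e-10 for both integration
  schemes.
* **Randomized plexus**: seeded jitter of root angles (±degrees) and
  segment lengths (±fraction) around the baseline, resampled on
  infeasibility, used for pipeline smoke-property tests. The jitters
  are test instruments, not a population model of neonatal anatomy:
  passing them shows robustness of the pipeline, not anatomical
  realism.

## Known limitations

* Linear elasticity at strains up to ~30% and a linear (small-strain)
  kinematic assumption: predicted strains are indicative only, and the
  soft-tissue toe region is not represented — the model is expected to
  under-predict deformation relative to nerve tissue.
* The 2D idealisation forces the trunks to lie in the cord plane and
  excludes out-of-plane force transmission.
* Middle and lower trunk displacements exceed the reference values
  (9.1 / 9.3 mm vs 3.8 / 4.3 mm); the drawn lower strips are longer
  than their anatomical paths because the merge-face construction fixes
  where the pair converges. Only engineering-strain arithmetic, not
  these magnitudes, is used in acceptance checks.
* Junction maxima are discretisation-tied (singular corners); compare
  them only at matched mesh sizes.
* The reconstructed anatomy is one member of the family consistent with
  the printed measurements; per-root conclusions sharper than the
  upper-vs-lower ordering should not be drawn from it.
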