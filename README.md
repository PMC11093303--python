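# plexusfem

A two-dimensional plane-stress finite-element model of the **neonatal
brachial plexus** — the C5–T1 nerve-root network injured in neonatal
brachial plexus palsy (NBPP) — for studying how tensile loading of the
nerve trunks stresses the proximal nerve roots, and how anatomical
variation in the root–cord angles changes that stress.

The package is aimed at injury-biomechanics researchers who want a
reproducible, scriptable re-implementation of this class of model:
parametric geometry, load partition, meshing, solving and
post-processing are plain Python (numpy/scipy), with every stage
testable against analytic oracles.

## The model

The spinal cord is a vertical elastic strip; the five nerve roots leave
its lateral surface as constant-width strips (widths = clinically
measured cranial-caudal root diameters) and merge into the upper
(C5+C6), middle (C7) and lower (C8+T1) trunks. Both tissues share one
isotropic linear-elastic material, with rate-matched properties from
neonatal piglet tensile tests:

| case | rate (mm/s) | F_fail (N) | E (MPa) | ν | p (MPa) |
|------|------------|-----------|---------|-----|---------|
| 1 (quasistatic) | 0.01 | 1.08 | 1.48 | 0.4 | 0.332 |
| 2 (dynamic)     | 10   | 2.12 | 2.02 | 0.4 | 0.653 |

A total tensile force of 5·F_fail is partitioned across the trunks by
composite theory: with equal modulus the share is proportional to
cross-sectional area, where each root's area is the ellipse
A = (π/4)·d_cc·d_t of its two measured diameters and trunk areas are
member sums. Because area enters both the partition and the
force-to-pressure conversion, every trunk carries the same distal
pressure p = 5·F_fail / ΣA (0.332 / 0.653 MPa above).

The domain is meshed with mapped bilinear quadrilaterals (CPS4-type,
full 2×2 Gauss integration; reduced single-point integration with
hourglass stabilisation is available behind a flag) at global size
bounds 2 mm / 0.2 mm. Boundary conditions: the cord midline is encastré,
the outermost lateral edges (superior C5, inferior T1) carry
symmetry-type guided supports, and p pulls normal to each distal trunk
face. The reported quantities are the maximum von Mises stress
σ_v = √(σ_xx² − σ_xx σ_yy + σ_yy² + 3 τ_xy²) at each root–cord junction
(contour-style nodal average at the interface), the distal-trunk
displacement, and the engineering strain 100·u/L₀ over the
cord-to-trunk path length.

The root–cord angles are not clinically measured; the bundled defaults
are a calibrated reconstruction (see `docs/methods.md`).

## Worked example

```bash
plexusfem validate --format csv --out results/
```

prints

```
[validate] wall=0.18s c5_case1_MPa=0.258 c5_case2_MPa=0.507 upper_disp_mm=7.68
```

and writes `validation_stresses.csv`:

```
,C5,C6,C7,C8,T1
case1:baseline,0.258,0.269,0.264,0.253,0.252
case2:baseline,0.507,0.529,0.52,0.498,0.495
```

Reading: under quasistatic loading the C5 junction sees 0.258 MPa, close
to the 0.200 MPa experimental single-root failure stress, and the upper
roots (C5/C6) are loaded more than the lower roots (C8/T1) — the
clinical injury pattern. Case 2 values are exactly case 1 scaled by the
pressure ratio 0.653/0.332 (linear elasticity; the check is asserted on
every run). `validation_trunks_case1.csv` adds the trunk table: the
upper trunk stretches 7.7 mm over its 41.4 mm path (18.5% engineering
strain).

The same pipeline is importable:

```python
import plexusfem as pf
from plexusfem.study import run_validation, run_angle_sweep

r1, r2 = run_validation()                # both load cases, one mesh
results, failures = run_angle_sweep()    # root angles ±3°, ±6°
print(results[6.0].percent_changes)      # per-root % change vs baseline
```

Other subcommands: `plexusfem sweep` (angle-variation table),
`plexusfem convergence` (uniform refinement study), `plexusfem
export-mesh` (Abaqus INP / legacy VTK).

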