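# expandep

Planning and quantification tools for electroporation with **deployable
expandable needle electrodes** — single-shaft devices whose four
peripheral needles (optionally plus a central one) fan out at a fixed
divergence angle α, so that a tumour can be treated in successive
deployment steps instead of requiring parallel needle placement.  The
package is aimed at medical physicists and device engineers who need to
reason quantitatively about such electrodes: which voltages to apply at
which deployment, what tissue volume the pulses cover, and how large the
resulting ablation is on imaging.

## What it computes

**Gap geometry.** With head offset `h_t`, base spacing `i`, needle
diameter `D` and exposure `e`, the centre-to-peripheral distance is
`r(e) = (e + h_t)·tan α + i/2`, and the free inter-needle gaps are

```
d/2 = r − D      (peripheral ↔ central, "semi-diagonal")
d   = 2r − D     (opposite peripherals, "diagonal")
side = √2·r − D  (consecutive peripherals)
```

**Voltage planning.** Pair voltage = gap [cm] × target field [V/cm],
rounded half-up to the generator granularity (1 V or 100 V).  Protocols:
reversible electrochemotherapy (8 × 100 µs pulses, 1000 V/cm) and
irreversible electroporation (80–120 × 100 µs at 5 kHz, ≥ 1500 V/cm).

**Field coverage.** A finite-volume solver for `∇·(σ∇φ) = 0` on a
regular 3D grid, with the needles' conductive segments as Dirichlet
electrodes and a field-dependent, irreversibly increasing conductivity
σ(|E|max) ∈ [0.1, 0.3] S/m.  Tissue whose accumulated maximum field
exceeds 400 V/cm counts as electroporated; segmented treatments
accumulate coverage as the union over deployment steps.

**Volumetrics.** Ablation size from imaging via the ellipsoid estimator
`V = (4/3)π·a·b·c` (maximum orthogonal diameters) and the voxel-count
estimator `V_CT = n_pixel·PS_o·PS_v·SBS` (NIfTI/NRRD masks with spacing
metadata).

**Phantoms.** Seeded generators for ellipsoid masks and closed-form
field scenarios (parallel plate, concentric shells, radial field) so
every stage can be validated against analytic ground truth.

## Worked example

Three electrode variants ship in the registry: `5n-0deg` (five parallel
needles), `4n-10deg` (four needles, 10° divergence) and `5n-20deg`
(five needles, 20°).

```python
>>> from expandep import get_model, gaps, Protocol, build_plan
>>> spec = get_model("4n-10deg").spec
>>> g = gaps(spec, 20.0)          # gaps at 20 mm deployment
>>> round(g.side_mm, 2), round(g.diagonal_mm, 2)
(7.59, 10.92)
>>> (plan,) = build_plan(spec, [20.0], Protocol.ire(1500.0), granularity_V=100)
>>> plan.voltage("side"), plan.voltage("diagonal")
(1100, 1600)
```

At 20 mm deployment the 10° electrode's consecutive needles sit 7.59 mm
apart and opposite needles 10.92 mm apart, so reaching 1500 V/cm
requires 1100 V and 1600 V across those pairs.  (The historically
quoted diagonal setting for this step was 1700 V; the package keeps the
rule-consistent 1600 V and records the mismatch in
`planning.KNOWN_PRINTED_DEVIATIONS` rather than absorbing it.)

Running `python examples/coverage_simulation.py` simulates the 20°
variant over 10/20/30 mm deployments on a coarse grid and prints:

```
after   10 mm step: step volume   4.32 cm^3, union   4.32 cm^3
after   20 mm step: step volume  16.90 cm^3, union  16.90 cm^3
after   30 mm step: step volume  39.22 cm^3, union  39.22 cm^3
```

— the electroporated union grows monotonically as the needles advance,
which is the point of segmented treatment.  The other scripts in
`examples/` walk through gap tables, full pulse plans, ablation
volumetrics and the phantom round trip, each printing the numbers it
computes and what they mean.

A thin CLI mirrors the library (`expandep geometry|plan|simulate|
volume|phantom`, see `--help`); exit codes are 0 success,
2 configuration error, 3 non-convergence, 4 I/O error.

## Layout

```
src/expandep/      geometry, planning, solver, volumetrics, phantoms,
                   registry, reporting, cli
examples/          one narrative script per capability
tests/             unit + property + end-to-end acceptance tests
docs/methods.md    models, assumptions, numerics, limitations
```
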