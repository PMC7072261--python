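# Methods

`expandep` models a deployable expandable needle electrode for
electroporation and the desk-scale computations around it: gap geometry,
voltage planning, electric-field coverage simulation, and ablated-volume
estimation.  This note records the models, the assumptions behind their
defaults, the numerical choices, and what the synthetic phantoms do and
do not establish.

## Electrode geometry

The electrode carries four peripheral needles on a square, optionally
plus a central needle on the shaft axis.  The peripherals leave a
virtual origin located a head offset `h_t` behind the shaft tip on a
circle of radius `i/2` (half the base spacing) and run at a fixed
divergence angle `α` from the axis.  At exposure `e` (the axial tip
depth beyond the shaft tip) the centre-to-peripheral-axis distance is

    r(e) = (e + h_t)·tan α + i/2.

The clinically relevant quantities are the free gaps between needle
surfaces, over which pair voltages are applied; they subtract one full
needle diameter `D` from the centre-to-centre distances:

    semi-diagonal  d/2  = r − D          (peripheral ↔ central)
    diagonal       d    = 2r − D         (opposite peripherals)
    side                = √2·r − D       (consecutive peripherals)

Defaults for the bundled variants: `h_t = 3 mm`, `i = 3.26 mm`,
`D = 0.45 mm`, active (uninsulated) needle segment 20 mm, maximum
deployment 40 mm.  This subtract-one-diameter reconstruction was chosen
because it reproduces every reference gap of all three bundled variants
to ≤ 0.01 mm; the widely circulated closed forms for `d` and `side`
contain a typographical loss (a radical dropped from a `1 − √2` factor)
and do not.  Two reference diagonals (14.44 and 17.98 mm at 30/40 mm
deployment of the 10° variant) were published with inconsistent
rounding — the formula gives 14.448 and 17.974 mm — and are matched to
0.01 mm rather than at 2-decimal equality.

`e` is interpreted as axial insertion depth (tip z-coordinate), not
needle arc length, consistent with the `tan α` form; the exposed needle
path length is then `(e + h_t)/cos α − h_t`, and the conductive segment
is the distal `min(20 mm, exposed length)` of the needle.  Reported
gaps round half-up to 2 decimals (this reproduces 10 of the 12
reference values exactly; the two exceptions above are flagged, not
chased).

The 3D layout (`needle_positions`) places peripheral tips at azimuths
45°/135°/225°/315° on radius `r(e)` at depth `e`; tip-to-tip distances
minus `D` reproduce the gap formulas to machine precision, and tests
hold the two code paths to < 1e−9 mm of each other.

## Voltage and pulse planning

The planned voltage for a pair is `gap [cm] × target field [V/cm]`,
rounded half-up to a granularity: 1 V for the zero-divergence variant
and 100 V for divergent variants (matching generator setting resolution
at high voltage; both granularities were inferred from the reference
voltage sets).  Regimes:

* reversible (electrochemotherapy, ESOPE-style): 8 pulses of 100 µs in
  two groups of four with polarity inversion, target 1000 V/cm;
* irreversible (IRE): 80–120 pulses of 100 µs at 5 kHz, target
  ≥ 1500 V/cm.

Pair census: the five-needle array drives 4 semi-diagonal plus 4 side
pairs (the central needle bisects the diagonal, so opposite peripherals
are not driven directly); the four-needle array drives 4 side plus 2
diagonal pairs.  The total pulse budget is split equally across
deployments and, within a deployment, across pairs, with remainders
assigned to the earliest buckets; only totals per treatment are
specified by the protocols, so the equal split is a package choice.

Two documented irregularities are preserved rather than absorbed:
the 10° variant's reported 1700 V diagonal setting at 20 mm deployment
is not rule-consistent (the rule gives 1600 V; see
`planning.KNOWN_PRINTED_DEVIATIONS`), and the 20° variant's reported
voltages correspond to an effective target near 900 V/cm rather than
1500 V/cm — they are reachable through the explicit preset
`5n-20deg-printed`, never by default.

## Field simulation

Tissue is a homogeneous isotropic conductor whose conductivity rises
irreversibly with the maximum field magnitude each point has
experienced, from σ_low = 0.1 S/m to σ_high = 0.3 S/m.  The transition
curve is not constrained by available reference data beyond its range,
so the default is a smoothstep between 400 V/cm (the
electroporation-success threshold, reused as the onset) and 800 V/cm
(saturation); both thresholds and a logistic alternative are
configurable, and all are declared as assumptions in every JSON report.

For each driven pair the stationary problem `∇·(σ∇φ) = 0` is solved
with the pair's needles as Dirichlet electrodes (+V and 0), all other
needles electrically inert, and an insulating outer boundary (far-field
conditions are not specified by the protocols; insulation is the
conservative choice for coverage).  Because σ depends on the field it
shapes, each pair runs a damped Picard fixed point
(solve → |E| → σ, relaxation 0.6, tolerance 1e−3 relative σ change,
max 25 iterations; plain iteration can two-cycle near the tolerance).
Pulses of different pairs are sequential in time, so pairs couple only
through the running per-node maximum |E|; inter-pair simultaneity is
not modelled.

Discretization: node-centred finite volumes on a regular grid
(default 0.5 mm spacing, domain = active-segment bounding box plus a
20 mm margin), 7-point stencil with harmonic-mean face conductivities,
Jacobi-preconditioned conjugate gradients at 1e−8 relative residual.
Needles (radius 0.225 mm, below the spacing) are rasterized as
one-node-thick Dirichlet polylines; this dilates the electrode radius
to roughly half a node spacing, a documented bias that shrinks under
refinement.  Field magnitudes come from central differences and are
reported in V/cm; internal units are mm, V, S/m.

Coverage at threshold `t` (default 400 V/cm) is the node count with
accumulated max |E| ≥ t times the node volume; a segmented treatment's
coverage is the union over deployment steps on a shared grid, which is
idempotent and monotone in the number of steps.  A separate check
(`verify_tip_field`) samples the accumulated field along straight
tip-to-tip segments against the 1000 V/cm design criterion; the two
thresholds express different criteria (design adequacy vs. coverage
accounting) and are never asserted against each other — tip-field
results are recorded per pair, pass or fail.

### Verification

* Parallel plate: linear potential and uniform |E| = V/L, reproduced to
  ~1e−8 (the discretization is exact for linear fields; errors are
  solver residual only).
* Concentric spherical shells, φ(r) = V·a(b−r)/(r(b−a)) with a = 2 mm,
  b = 10 mm: the default oracle realization fixes two ≈ 2h-thick
  spherical bands carrying the closed form at each node's exact radius
  (the extended C₁ + C₂/r form is harmonic away from the origin), so
  the measured error isolates the discrete operator from the staircase
  radius bias of voxelized electrodes.  At 0.5 mm spacing the potential
  error is < 2 % in max norm over the annulus (measured ≈ 0.2 %) and
  the RMS error decreases under 1.0 → 0.5 mm refinement by more than a
  factor 2 (observed order ≈ 1.7).  The field-magnitude comparison uses
  RMS over the annulus (< 2 %, measured ≈ 0.5 %) because the pointwise
  central-difference truncation of the 1/r² field scales as (h/r)² and
  peaks at ~4 % right at the inner radius — an intrinsic property of
  the gradient stencil, not of the solve.  The solid-electrode
  ("constant") realization is also exercised: it obeys the discrete
  maximum principle and carries the expected O(h) effective-radius bias
  (~8 % at 0.5 mm), which is why it is not the oracle of record.
* Conservation: the net discrete current through every grid plane
  separating the two electrodes of a driven pair agrees to < 1e−6
  relative spread (solver tolerance).
* Monotonicity: coverage is non-increasing in threshold and
  non-decreasing in applied voltage; σ is bounded in [0.1, 0.3] S/m and
  element-wise non-decreasing over the pulse sequence and across
  deployments.

Problem sizes: the oracle scenarios run on their natural small domains
(≤ ~90k nodes) at 0.5 mm; the segmented three-deployment study of the
20° variant runs at 2 mm spacing with a 12 mm margin (~15k nodes),
which is sufficient for the qualitative union-monotonicity result it
demonstrates.  Finer grids change the coverage numbers by the
documented rasterization bias but not the monotonicity structure.

## Volumetrics

Two estimators quantify an ablation from post-treatment imaging:

* `V_ellipsoid = (4/3)π·a·b·c` from the three maximum orthogonal
  diameters (semi-axes a, b, c in cm);
* `V_CT = n_pixel · PS_o · PS_v · SBS` from the segmented pixel count
  and the voxel footprint, where the slice pitch SBS absorbs any
  inter-slice gap (ST + (SBS − ST)); overlapping acquisitions
  (SBS < ST) are accepted and flagged.

Mask diameters use the voxel-inclusive extent convention
`(max_index − min_index + 1) × spacing` with 0-based indices (the
convention is not fixed by the estimator definitions, so it is pinned
here).  NIfTI and NRRD masks are read through nibabel and SimpleITK;
image headers carry only the slice pitch, so a JSON sidecar or explicit
arguments can supply a distinct slice thickness.

One dataset-level inconsistency is surfaced deliberately: reference
V_CT totals quoted with PS = 0.9766 mm (2.38/6.99/10.13 cm³ for
n_pixel = 990/2911/4218 at SBS = 2.5 mm) are exactly consistent with
PS = 0.98 mm instead (0.9766 mm gives 2.36/6.94/10.06 cm³).  The
package computes both and reports both; it never silently corrects
either spacing.

## Synthetic phantoms

`make_ellipsoid_mask` builds ellipsoidal masks by voxel-centre
inclusion (no partial-volume weighting), keeping the pixel count an
exact integer that is a pure function of parameters and seed.  Optional
noise flips boundary-layer voxels only (inner erosion shell plus outer
dilation shell), each with probability `amplitude / layer size`, so the
expected flip count equals the requested amplitude and the topology
survives.  The mask voxel count converges to the analytic (4/3)πabc
volume as spacing shrinks (≤ 2 % at 0.125 mm on the reference
diameters, ≈ 0.02 % at 0.2 mm).

What the phantoms do not emulate: CT noise texture, partial-volume
blur, contrast-dependent segmentation bias, heterogeneous or
anisotropic tissue, and electrode–tissue interface impedance.  Passing
the phantom suites therefore establishes the correctness of the
implemented estimators and solver on their stated models, not the
fidelity of those models to in-vivo ablations.

## Known limitations

* Thermal (Joule) effects, electrode polarization and arcing are out of
  scope; the field model is quasi-static and purely conductive.
* The σ(E) transition thresholds are assumptions; coverage volumes move
  with them and reports always restate the values in force.
* Needle rasterization at default spacing overstates the electrode
  radius by up to half a node; refine the grid when absolute coverage
  (rather than comparisons across plans) is the quantity of interest.
* The pulse-budget split across pairs and deployments is an even
  allocation by construction, not a measured protocol.
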