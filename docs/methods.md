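# Methods

## The model

`synbuckle` simulates the mechanics of exo–endocytic coupling at a
presynaptic terminal.  The plasma membrane of the terminal is a patch
containing three material domains: the membrane of freshly fused synaptic
vesicles (stiff, bending modulus κ₁), the active zone together with the
surrounding endocytic zone (soft, κ₂), and the actin-enriched periactive
zone (stiff, κ₃ = κ₁ by default) whose outer rim is anchored.  The
mechanical energy is a Helfrich-like functional

    E = Σᵢ ∮ dsᵢ [ 2 κᵢ (Ω − Ω₀)² ]  +  Π·V

with Ω the mean curvature (positive toward the cytoplasm), Ω₀ the
spontaneous curvature (0 by default), Π an osmotic-pressure penalty and V
the volume displaced inward from the flat baseline.  Shape relaxation is
the overdamped gradient flow

    η ∂h/∂t = −δE/δh

subject to three constraints: (i) the total membrane area is conserved,
with the membrane tension λ as the Lagrange multiplier — this encodes the
actin ring's impediment of lipid flow out of the terminal; (ii) the outer
rim of the periactive zone is pinned at h = 0; (iii) only inward (toward
the cytoplasm) deflections are allowed, h ≥ 0, reflecting the apposed
postsynaptic membrane.

The biological question encoded in the model: fused vesicles arrive as
stiff, nearly-halfway-collapsed domes (40-nm vesicles, ~26 nm initial
apex depth).  Flattening them under conserved total area forces the soft
zone to buckle, and a pit whose mean curvature exceeds c* = 0.03 nm⁻¹ is
scored as a successful hand-off to curvature-sensing endocytic proteins.
The simulation stops at pit formation; fusion-pore chemistry and scission
are outside the model.

## Discretization

The membrane is a Monge-gauge height field h(x, y) ≥ 0 over a fixed flat
reference triangulation (concentric-ring disc mesh; near-equilateral
elements within ±50% of the target edge length).  Material labels live on
reference faces and are fixed for a run; the initial fused-vesicle domes
are spherical caps (default: hemispheres of depth 26 nm) imprinted on the
height field.

* **Area** is the exact area of the piecewise-linear embedded surface;
  **volume** is the exact prismatic integral of h.
* **Mean curvature** uses the discrete curvature-normal construction on
  the embedded surface: the per-vertex 3D gradient of the total area
  (which is the cotangent-Laplacian applied to the embedding) projected on
  the area-weighted vertex normal and divided by twice the lumped embedded
  vertex area.  This estimator stays accurate at near-vertical slopes
  (hemisphere identity 4πκ met to ~2% at edge = R/10); boundary vertices
  lack a full stencil and report 0.
* **Bending energy** samples (Ω − Ω₀)² at vertices and weights each face
  by its embedded area spread over its interior corners.
* **Gradients are exact**: a hand-written reverse-mode pass through the
  curvature-normal construction differentiates the discrete energy itself,
  so finite-difference checks converge to ~1e-8 relative and descent of
  the discrete functional is guaranteed by construction.

## Constrained integration

The default stepper is semi-implicit: each step solves

    (η·M + dt·(B + λq·L)) δ = −dt·(g − λ·a)

on the free vertices, where M is the lumped reference-area drag metric, B
the bending Hessian linearized at the flat state (assembled from the
reference cotangent stiffness L), and λq a quantized copy of the current
tension.  The λq·L term is a convexity splitting: membrane tension is the
*destabilizing* term during buckling (growth rate λk² − κk⁴), and treating
it implicitly bounds the per-step growth of the unstable band at any dt.
The tension λ itself is determined each step by root-finding the
total-area constraint *through* the inward-only clamp,
area(clamp(h + δ(λ))) = A₀, followed by a uniform-rescale polish to
relative tolerance 1e-12 (trace area errors sit far below the 1e-6 bound).
A trial step is accepted only if the energy does not increase beyond
1e-10·|E|; otherwise dt is halved (factorizations are cached per (dt, λq)).
dt doubles after every few accepted steps, so the scheme is adaptive in
both directions.  An explicit stepper with the classical biharmonic bound
dt = safety·η·ℓmin⁴/κmax (safety 0.1) is available (`method="explicit"`)
and used in tests as a cross-check; it is ~10⁴× slower to converge and not
the default.

Runs stop at a hard time limit, when the energy changes by less than 1e-8
(relative) across a 200-accepted-step window, or when backtracking reaches
the arithmetic floor of the constraint projection with a flat energy
history ("gradient_floor" — convergence to the discrete minimum).

## Parameters, units, calibration

Lengths are nm, energies k_BT, pressure k_BT/nm³, moduli k_BT.

| parameter | default | meaning / rationale |
|---|---|---|
| κ₁ | 300 | fused-vesicle membrane modulus (nominal of the 100–400 range) |
| κ₂ | 20 | active-zone modulus (soft; within the 10–100 range) |
| κ₃ | κ₁ | periactive modulus (actin-stiffened) |
| Ω₀ | 0 | spontaneous curvature |
| Π | 5e-4 | ≈ 2 kPa; sets the pit length scale (κ₂/Π)^¼ ≈ 14 nm, matching the tens-of-nm dimensions of ultrafast endocytic pits.  Π is not printed in the available text; this one-time choice is held fixed across every scenario.  Much smaller Π lets the stored area spread into a single broad ~100-nm bump with curvature far below c*. |
| η | 1 | drag; sets the unit of simulation time (η·nm⁴/k_BT) |
| c* | 0.03 | pit-success mean-curvature threshold, strict inequality |
| L | 500 | active-zone diameter (100–700 supported) |
| w | 100 | periactive band width (the alternative 50 is config-selectable) |
| target_edge | 8 (runs), 10 (sweeps) | mesh resolution |
| δ_pit | 2 | pit detection height threshold, nm |

**Time calibration and effective-time semantics.**  Physical time is
integrated in units of η·nm⁴/k_BT.  One calibration constant (ms per time
unit, frozen in ``dynamics.DEFAULT_MS_PER_TIME``) maps it to milliseconds;
it is fixed once so that the nominal three-vesicle scenario first
satisfies the pit-curvature criterion near 30 ms under the default
protocol, and all other scenarios and event timestamps (e.g. conservation
release at 2/5/12 ms) inherit it unchanged.  An important caveat: at
large dt the semi-implicit update saturates toward a bounded quasi-Newton
move while the clock still advances by dt, so late-trajectory times are
*effective*, not literal drag-flow times.  The clock is consistent within
the fixed protocol (which is all the single calibration requires), and a
trajectory-faithful mode is available for dynamics-sensitive questions:
``run(..., dt_max_frac=0.05)`` caps every step at 5% of the elapsed time
(logarithmic resolution of the relaxation); the conservation-release
experiments are evaluated in this mode.

**Default protocol.**  Scenario runs report the state at the calibrated
120 ms horizon (roughly twice the ~58 ms timescale on which the
experimental system reaches its steady configuration) unless the windowed steady-state criterion fires
first.  There is no practical ε-stationary point to run to instead: the
landscape's positional near-zero modes give dissipative coarsening tails,
so every reported state is a finite-horizon state by necessity.

## What the scenarios emulate — and what they do not

Scenario presets place hemispherical domes at the geometry of the source
experiments (three vesicles at (0, 60), (±60, −60); two at ±60; rings for
N ≥ 4, reported alongside any phase diagram) inside the active-zone disc,
with conservation on and the rim pinned.  Events can release/resume area
conservation and fuse additional vesicles at a time or when the first
dome's apex passes a depth trigger.

Two deliberate idealizations of the height-field representation matter
when interpreting results:

1. **No lateral material transport.**  Material labels are fixed in
   reference coordinates; lipids cannot flow sideways.  In a
   deformable-mesh treatment the flattening stiff domes spread and push
   the soft membrane against the stiff periactive ring, which is what
   localizes endocytic pits at the active-zone edge.  Here pit position is
   close to energetically degenerate (relaxed single-pit energies: center
   138 k_BT, mid-zone 150, near-interface 149 at nominal parameters), and
   pits instead form adjacent to the vesicle cluster where the area is
   released.  Pit *counts*, *curvatures* and *success thresholds* are the
   meaningful observables of this implementation; pit *radial position* is
   not, and the interface-distance column in pit reports documents the
   difference rather than hiding it.
2. **Slow coarsening beyond the observation window.**  Because position
   is nearly degenerate, the late-time flow slowly migrates and merges
   pits (two pits → one structure hugging a dome) well past the
   pit-formation stage.  The biological model hands off to endocytic
   proteins once c* is exceeded, and the relevant experimental window
   extends to ~58 ms; the 120 ms default horizon reports the configuration of that
   era rather than the deep coarsening limit.
3. **Stiffness dependence is muted.**  In the deformable-mesh original,
   pits fail when the vesicle membrane is too soft (it cannot transmit
   lateral compression) or the active zone too stiff.  With frozen
   labels, a soft dome instead crumples in place and the adjacent soft
   membrane develops sharp features that the pit detector legitimately
   reports; the bending-moduli failure boundaries (κ₁ ≈ 230, κ₂ ≈ 50
   k_BT) and the vesicle-number/size phase boundaries therefore do not
   reproduce here, and neither does sub-10% mesh-refinement stability of
   the transient pit curvature.  What does reproduce: pit formation by
   vesicle cooperation with curvature at the 0.03–0.06 nm⁻¹ scale (two
   pits for the nominal triangle), the clean failure of a single fusion,
   the decay of pits when area conservation is released (faithful mode),
   sequential-fusion rescue, and the independence of well-separated
   fusion events.

The synthetic scenarios contain no stochasticity: runs are deterministic
for a given spec and resolution (symmetry is broken only by the mesh).
Passing tests therefore say nothing about robustness to thermal noise or
to disorder in vesicle positions beyond what the spacing presets probe.

## Pit analysis

Pits are connected components of {h > δ_pit} on non-vesicle membrane.
Vesicle faces plus a 1-ring margin are excluded, and additionally every
vertex within √2·a of a vesicle center (a the dome rim radius): a fully
flattened cap of rim a covers exactly that footprint with its conserved
area, so membrane inside it is vesicle-derived material — the collapsing
exocytic dome and its slump skirt are not endocytic structures.  Per pit: area-weighted centroid, max
depth, max vertex mean curvature, distance of the centroid to the
active-zone/periactive interface circle (recovered from the face labels).
The headline observable is the maximal pit mean curvature *at the time of
maximal pit depth* over the run; success is a strict comparison against
c*.  Threshold boundaries in parameter scans are located by a monotone
bisection over the grid (`threshold_scan`) and reported at the
failure→success transition.

## Numerical choices and degenerate inputs

* A₀ is the *meshed* initial area (flat mesh + imprinted domes), so the
  constraint is exactly satisfiable on the discrete surface; fusion events
  add the measured meshed area change of their imprint.
* Dome rims aligned with mesh rings avoid aliasing the rim slope kink;
  dome footprints are assigned to faces by centroid position.
* The 1D axisymmetric oracle uses the same energy, constraints and
  minimizer on a dense radial grid (Δr ≤ 0.25 nm), with exact frustum
  areas and an axis-node curvature mass πΔr²/4 (exact for parabolic
  caps).  Its remaining bias is the vertical-rim discretization of a
  hemisphere (~1% in bending energy at Δr = 0.02).
* Flat states with conservation on have a vanishing area gradient; the
  tension defaults to 0 there.  Exactly-at-threshold curvature (0.030)
  classifies as failure (strict inequality, documented tie-break).
* Mesh snapshots export as OBJ and legacy-VTK ASCII with height, mean
  curvature and material label attached.

## Known limitations

* Overhanging shapes (Ω-profiles, necks) cannot be represented; the model
  stops at pit formation, consistent with that limit.
* Pit radial localization at the active-zone edge — a kinematic effect of
  lateral material flow — is outside the representable physics (see
  above); quantitative thresholds that depend on it may shift relative to
  a deformable-mesh treatment.
* No thermal fluctuations, hydrodynamics, lipid/protein diffusion, or
  protein-mediated spontaneous curvature.
* Timestamps in milliseconds are meaningful only relative to the single
  η calibration; absolute times depend on the unavailable drag value.
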