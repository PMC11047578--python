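# Methods

`vasculate` is a headless toolkit for reduced-order (1D–0D) hemodynamic
simulation on image-derived vascular networks: voxel skeletonization,
centerline smoothing, pulse-wave simulation with lumped terminals and
stenosis elements, wall-shear-stress post-processing, constant-WSS
remodeling, and dynamic lumen-mesh export. This note records the models,
the numerical choices, and what the synthetic fixtures do and do not
establish.

## Geometry pipeline

**Skeletonization.** Binary vessel volumes are thinned to one-voxel-wide
centerlines with the topology-preserving 3D parallel thinning of Lee et
al. (1994) as implemented in scikit-image; the algorithm name is recorded
in the skeleton metadata. Thinning runs in index space; anisotropic
spacing is accepted with a logged warning. Voxels are nodes at their
world-space centers (`origin + index * spacing`, mm), adjacency is
26-connected. Clusters of mutually adjacent degree-≥3 voxels — a common
thinning artifact at branch points — are collapsed to a single node at
their centroid so the graph has clean terminal (degree 1), plain
(degree 2) and bifurcation (degree ≥ 3) nodes; an isolated voxel is a
terminal by convention. Segments are maximal bifurcation-free paths,
labeled by integer arterial index; a pure cycle becomes one closed
segment. Pruning removes terminal-ended segments shorter than a length
threshold (or labels outside a keep-set), reclassifies the touched
bifurcations, and merges through-chains; merged segments inherit the
smallest surviving label so relabeling is stable.

**Local radius.** How a node radius should be derived from the image is
genuinely open; we use the Euclidean distance transform of the
foreground (spacing-aware), sampled at the node voxel — i.e. the
distance to the nearest background voxel. This matches the "maximal
inscribed sphere" reading of a local radius and is exact against
brute-force nearest-background search (tested on ≤32³ volumes). Note
thin even-width structures can be erased entirely by Lee thinning; the
skeletonizer raises a diagnostic rather than returning an empty graph,
and phantoms keep tube radii ≥ 2 voxels.

**Smoothing.** Medical-image quantization shows up as jitter that wrecks
polyline curvature estimates. Each labeled segment is fit, per
coordinate and for the radius channel, with a degree-5 B-spline in a
chord-length parameter, penalized by
`lam3 * ∫(f‴)² + lam4 * ∫(f⁗)²`. Knots sit at every 3rd data point;
penalty Gram matrices are assembled by per-span Gauss–Legendre
quadrature (exact for the polynomial integrands). The penalty weights
are selected from a logarithmic grid (1e-4…1e2, 13 values, searched on
the diagonal lam3 = lam4 by default, full grid optionally) by minimizing
`AIC = Σ_channels n ln(RSS/n) + 2·m·edf`, where `edf` is the trace of
the smoother matrix and m = 4 channels share one smoother. Because the
knot set is coarser than the data, the lam→0 limit reproduces the data
to ~1e-2 mm, not machine precision; exactly collinear input is
reproduced exactly (a line lies in the basis span with zero penalty).
On the noisy-helix fixture this fit cuts RMS curvature error by ~94%
relative to the raw polyline (the acceptance suite asserts ≥50%).

**Resampling.** The fitted curve is reparameterized to arc length: the
total length comes from adaptive quadrature of the parametric speed
(relative tolerance 1e-6) and the inverse arc-length map from a dense
composite-Simpson table scaled to that total, so both endpoints are
exact. Points are placed at 0, Δl, 2Δl, …, L with the final point always
included; Δl defaults to 2 mm. The chord-sum of the resampled polyline
undercuts the true arc length by ≈(κΔl)²/24 — about 0.17% on the helix
fixture — which is geometry, not error; the arc-position grid itself is
exact.

**Network assembly.** Segment ends attach to exactly one junction, the
single inlet, or a terminal; junction endpoints are snapped to their
common centroid when all lie within 1.5·Δl of it (skeleton and spline
endpoints drift by about a voxel), otherwise assembly fails loudly.
Networks round-trip through documented JSON bit-identically.

## 1D–0D solver

**Model.** Each vessel is an axisymmetric compliant tube governed by the
cross-sectionally averaged continuity and momentum equations

    A_t + Q_z = 0
    Q_t + (Q²/A)_z + (A/ρ) P_z + K_R Q/A = 0

closed by the elastic tube law `P − P0 = β(√(A/A0) − 1)` with
`β = E h0 / (r0 (1 − σ²))`. The local wave speed is
`c = √(β √A / (2 ρ √A0))`, equal to the Moens–Korteweg speed
`√(E h0 / (2 ρ r0 (1 − σ²)))` at `A = A0`. Defaults: ρ = 1060 kg/m³,
μ = 0.004 Pa·s, σ = 0.5, P0 = 85 mmHg, E = 400 kPa, h0 = 0.3 mm — all
config-overridable, globally or per segment (h0 may also be specified as
a ratio of the local radius). The friction coefficient `K_R` defaults to
22πν (a flattened velocity profile, the convention of systemic-network
1D models) with 8πν (Poiseuille) selectable. Internally everything is
SI; geometry I/O is mm, flows ml/s, pressures mmHg.

**Interior scheme.** Richtmyer two-step Lax–Wendroff in conservative
form with flux `F = (Q, Q²/A + β A^{3/2}/(3ρ√A0))`, a friction source
`−K_R Q/A`, and well-balanced taper sources for along-axis variation of
β and A0 (derived so the rest state A = A0(z), Q = 0 is an exact
analytic equilibrium). Δs defaults to 1 mm; each network segment is
discretized with the nearest integer node count. CFL number defaults to
0.5. Within `simulate` the time step is fixed per cardiac cycle (so
output sampling is uniform); because systole accelerates the waves, the
step is chosen with an adaptive headroom margin over the largest
eigenvalue rate seen so far, and a mid-cycle CFL violation rolls the
cycle back and retries with a wider margin. The public single-tube
stepper instead raises with a suggested dt. Nonpositive areas abort with
a "collapse" diagnostic; NaNs abort naming segment and time — never a
silent NaN.

**Coupling.** Segment ends communicate through Riemann invariants
`W± = u ± 4(c − c0)`, evaluated at the foot of the outgoing
characteristic (linear interpolation one time level back).

* *Junctions* enforce mass conservation and static-pressure continuity
  (total-pressure continuity is a config option). With the tube law
  invertible in closed form, all incident areas are functions of the one
  junction pressure, so each junction is a scalar Newton solve; the mass
  residual is driven below 5e-18 m³/s (5e-12 ml/s), and the largest
  defect seen in a run is reported.
* *Inlet*: prescribed periodic inflow Q(t) (tabulated; default half-sine
  systole over 0.35 T) combined with the outgoing invariant — scalar
  Newton for the boundary area.
* *RCR terminals*: three-element Windkessel. The capacitor pressure
  advances by implicit Euler,
  `dP_c/dt = (Q − (P_c − P_out)/R2)/C`, and the terminal pressure
  `P = P_c + R1 Q` is solved simultaneously with the outgoing
  invariant (scalar Newton in the boundary area). A non-reflecting
  terminal (incoming invariant pinned to rest) is available for wave
  experiments.
* *Stenoses* are internal interfaces with continuous flow and a pressure
  jump of Young's empirical form
  `ΔP = (Kv μ/(2 r0 A0)) Q + (Kt ρ/(2A0²))(A0/As − 1)² Q|Q|
  + Ku ρ Ls/A0 · dQ/dt`,
  with defaults `Kv = 32 (Ls/2r0)(A0/As)²`, `Kt = 1.52`, `Ku = 1.2`, all
  exposed in config. The element splits its segment into two solver
  tubes joined by a 2×2 Newton face; dQ/dt is backward-differenced.

**Cycle convergence.** Cardiac cycles repeat until the pressure field
sampled at the output stride changes by less than 1e-3 (relative to the
peak pressure) between consecutive cycles, capped at 20 cycles (a capped
run is returned flagged with a warning). Windkessel capacitors are
initialized at their conductance-weighted steady values so the transient
is short (the loop fixture converges in ~7 cycles). The conservation
report includes the per-cycle volume budget — inlet volume vs terminal
outflow plus stored-volume change — which closes to ~0.02% on the loop
fixture (asserted < 0.5%).

**Verified behavior** (all computed by the test suite): a 1% area pulse
propagates at the Moens–Korteweg speed within 0.5%; reflection off a
non-reflecting outlet is < 0.1% of the incident amplitude; halving Δs
moves peak pressures by < 1%; a tube split by a degree-2 junction has
the same frictionless steady state as the unsplit tube to 1e-8 (the
transient fields differ at the face's O(Δs²) truncation level, so the
splice oracle is posed at the shared fixed point).

## Post-processing

Mean velocity `V = Q/A`; cross-section profile by Hagen–Poiseuille,
`U(r) = 2V(1 − r²/R²)`; wall shear stress `τ_w = 4 μ V / R`, which is
exactly `μ|dU/dr|` at the wall. The WSS radius uses the instantaneous
area (`R = √(A/π)`) by default, reference radius optionally. TAWSS is
the cycle mean of `|τ_w|` (trapezoidal, with periodic closure of the
sampled cycle); a signed mean is available by flag. Note an inherited
modeling inconsistency, deliberately left exposed rather than resolved:
the momentum friction default (K_R = 22πν) corresponds to a flatter
profile than the Poiseuille assumption used for WSS; both knobs are
independent in config.

Solver fields map onto 3D centerline points by linear interpolation in
arc length (endpoints exact, via an affine arc map between the solver
tube and the centerline); mismatched arterial indices or a >5% length
discrepancy are errors.

## Lumen meshes

Frames along a segment use central-difference tangents and
rotation-minimizing parallel transport (the double-reflection method),
which is twist-free on planar curves and has zero holonomy on closed
planar loops. Ring vertices sit at radius `√(A/π)` at angles `2πl/k`
(k defaults to 16). Consecutive rings are stitched by pairing each
vertex with the Euclidean-nearest vertex of the next ring — a constant
circumferential offset; ties break to the lower index, and a
non-monotonic per-vertex pairing (twist beyond half a slot) falls back
to the constant offset with a warning. Each band contributes 2k
triangles with consistent outward winding; a single segment with N
rings has exactly kN vertices and 2k(N−1) faces, V − E + F = 0. Tubes
are left open at junction ends (no junction capping). Animated meshes
rebuild vertex positions per frame from the instantaneous A(s,t)
(static geometry optional) and carry per-vertex scalars; exports are
byte-deterministic ASCII legacy-VTK or PLY files plus a PVD-style XML
time index and a JSON color-range sidecar.

## Remodeling

Arteries adapt toward homeostatic WSS. Since `τ_w = 4μQ/(πr³)` at fixed
flow, the constant-WSS fixed point is `r* = r (τ/τ*)^{1/3}`; the outer
loop applies `r ← r (τ̄/τ*)^{ω/3}` (ω default 0.5, per-step factor
clipped to [0.7, 1.5]) to each adaptive segment's reference radius,
re-simulating between updates (warm-started from the previous run, with
stored areas rescaled to the new reference), until the segment-mean
TAWSS matches the target within tolerance (default 5%, cap 12
iterations). Targets may be given per segment or computed from a
baseline run (the same network with stenoses removed, or an explicit
reference network). Wall thickness stays fixed unless `scale_h0` is set.
Divergence (error growing three consecutive iterations) aborts with the
trace. On the rigid Poiseuille toy, ω = 1 converges in one step and
doubling the flow yields the radius ratio 2^{1/3} to 0.003%; on the loop
fixture the overloaded collateral (TAWSS 2.8× baseline) returns to
baseline within tolerance while its radius grows ~1.47×.

## Synthetic fixtures: what they are and are not

The fixtures module generates every input the tests need,
reproducibly from (parameters, seed): capsule-voxelized tube/Y/helix
phantoms with analytic ground truth (helix curvature
`κ = R/(R² + c²)`, c = pitch/2π); quantization-noise centerlines
(uniform jitter, optional grid rounding); half-sine inflow waveforms
whose trapezoidal integral equals the stroke volume exactly; and a
planar toy looped network reminiscent of the circle of Willis.

The toy loop is two inlet branches fed by one root, joined by left and
right communicating segments that meet at a midline junction feeding
two distal terminals — four RCR terminals, one cycle. Its constants are
fixture choices at cerebral scale, not patient data: root radius 4 mm,
inlet branches 3 mm, MCA-like branches 2 mm, communicating segments
1.5 mm, lengths 20–60 mm; E = 400 kPa with h0 = 0.15·r0 (so β and the
wave speed are uniform); MCA terminals R1 = 4e8, R2 = 2.46e9 Pa·s/m³,
C = 3.5e-10 m³/Pa, distal terminals at twice those resistances and half
that compliance (smaller territories); venous pressure 5 mmHg; stroke
volume 12 ml over T = 1 s (mean pressure ≈ 86 mmHg); solver CFL 0.8.
The distal-bed asymmetry matters: it leaves the midline junction free to
float between the two sides, so a severity-0.9 inlet stenosis produces
genuine retrograde collateral flow (+2.0 → −1.8 ml/s) rather than mere
attenuation. Stenosis severity is by area; the NASCET diameter
convention maps through `area severity = 1 − (1 − NASCET)²`, and presets
"CS" (70% NASCET ⇒ 0.91 area) and "VRCA" (0.90 area) are provided.

What passing these tests shows: the coupled solver machinery —
junctions, loop, terminals, stenosis element — reproduces the expected
collateral physics, conservation, and remodeling fixed points on a
clean, symmetric, planar network with uniform wave speed. What it does
not show: fidelity on patient anatomy (tapered, tortuous, 3D,
asymmetric networks with measured terminal parameters), wall
viscoelasticity, closed-loop heart/venous coupling (the inflow is
prescribed), or imaging artifacts beyond uniform quantization jitter.

## Problem sizes and runtime

Defaults are sized so the full suite runs comfortably on one CPU: the
loop fixture has ~330 solver nodes and converges in ~7 cycles of ~9k
steps (~40 s per run); remodeling runs one baseline plus ≤10 warm-started
outer simulations; wave experiments use single tubes of 400 nodes for a
few hundred steps. The acceptance script repeats the same computations
from scratch in about 3 minutes.

## Known limitations

* Static-pressure junction continuity ignores junction losses; the
  total-pressure option exists but no empirical loss model.
* The stenosis element's coefficients are empirical defaults; nothing
  calibrates them per patient.
* Segment-mean steady flows carry ~0.1% ripple at the default
  cycle-convergence tolerance; tighten `conv_tol` when probing below
  that.
* The WSS/friction profile inconsistency described above is inherent to
  this model family's common usage and is surfaced, not resolved.
* Heterogeneous ring resolution (different k per ring) and junction
  capping surfaces are out of scope for the mesh builder.
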