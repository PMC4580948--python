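# Methods

`oostream` models how a disordered, cortically nucleated microtubule (MT)
cytoskeleton polarises the stage 9 *Drosophila* oocyte, drives slow
cytoplasmic streaming, and localises mRNA cargo. This note records the
models, the numerical choices, and what the package's tests do and do not
demonstrate.

All computation is nondimensional with length scale L = 50 µm, velocity
scale V = 0.5 µm/s (measured active transport speed) and time scale
τ = L/V = 100 s. Internally the anterior–posterior (AP) axis is the z axis
everywhere; serialized fields are relabelled so the AP axis becomes x only
at export (`io.ap_axis_to_x`), which keeps one orientation convention in
all numerics.

## Geometry

The oocyte is the closed volume between two rotationally symmetric
parabolic caps, σ_i(ρ,φ) = ρ ê_ρ + z0_i(1−ρ²) ê_z with z0_A < z0_P.
Preset `geometry1` (z0_A = 0.2, z0_P = 1.48) gives AP length 1.28 and
aspect ratio 1.56; `geometry2` (flat anterior disc, z0_A = 0) is the
robustness-check shape. Arclength, surface measure, cap areas and volumes
have closed forms that the tests cross-check against quadrature at 1e−8.

Two consequences of this shape are easy to get wrong and are handled
explicitly:

* the **inward posterior normal** is −(2 z0_P ρ ê_ρ + ê_z)/√(1+(2 z0_P ρ)²)
  — the volume lies *below* the posterior cap, so the normal at the
  posterior pole is −ê_z;
* the domain extends **below the anterior apex plane** near the equator
  (z < z0_A for ρ → 1, 13.5% of the volume in geometry-1, containing the
  high-density anterior corners). All regular grids therefore span
  z ∈ [0, z0_P]; clipping the grid at z0_A silently discards
  anterior-corner MT segments and biases flow statistics by ~6%.

Membership tests are boundary-inclusive with tolerance 1e−12 because seed
points lie exactly on the surface.

## Cortical seeding

Seeding density along cap arclength s:
p̃(s|h0,k) = h0 + (1−h0)(1+(k/s0)²) s²/(k²+s²), with p̃(s0) = 1 at the
corner ring on every cap, making the density continuous across the
anterior/posterior contact line. Wild type: h0_A = 0.8, k_A = 20 (shallow
anterior gradient), h0_P = 0, k_P = 3 (steep posterior-lateral gradient,
zero at the pole). The *par-1* hypomorph series flattens the posterior
density (k_P = 0.35, k_P = 0.02, and h0_P = 0.7/k_P = 0.8).

Sampling is per-cap inverse transform: the CDF over ρ is tabulated on 4096
Chebyshev-spaced nodes (cumulative trapezoid of the surface density) and
inverted with a monotone PCHIP interpolant; φ is uniform. The posterior
count follows from matching ring densities at the contact line,
N_P = N_A·A(h0_P,k_P)/A(h0_A,k_A) with A the per-cap integral of p̃ dΣ,
rounded to nearest. With N_A = 25000 this reproduces the wild-type total
N = 55764 exactly; sampling per cap with these counts is distributionally
identical to sampling the globally normalized density (verified by a
rejection-sampling oracle and two-sample KS test). Closed-form alternative
densities (power-law gradient, uniform-by-area) are provided with their
analytic inverses and count-matching formulas.

## MT polymers

Each seed grows one persistent random walk of segments of fixed
nondimensional length λ = 0.015 (0.75 µm). λ is dimensionless: only this
reading is consistent with the quoted effective persistence length
P ≈ λκ·L = 13.5 µm at κ = 18. The first orientation is uniform on the
inward hemisphere — implemented by reflecting outward uniform-sphere draws
through the tangent plane, which realizes the same law as rejection — and
subsequent orientations follow a von Mises–Fisher (vMF) distribution about
the previous one, sampled by the inverse-CDF polar-cosine method
(w = 1 + κ⁻¹ log(u+(1−u)e^{−2κ})).

Target lengths follow the length law of a growing MT population whose
catastrophe lengths are Erlang(3) ("three-step aging"): CDF
Φ(l) = 1 − e^{−l/Λ}(6Λ²+4lΛ+l²)/6Λ², mean 2Λ, with Λ = ε·(AP length)/2.
We sample it exactly through its mixture representation (an equal-weight
mixture of Erlang(1..3), i.e. l = Λ·Gamma(K,1) with K uniform on {1,2,3}),
which is distributionally identical to inverting Φ; the tests verify this
against the analytic CDF by KS. An exponential law with the same mean is
available.

Growth terminates when a new segment's endpoint exits the geometry (the
exiting segment is dropped; no clipping or reflection), when the chain
length reaches the target (checked after adding each segment), or at
Ns_max = 200 segments (<5% of wild-type polymers reach the cap). Chain
analytics used as oracles: σ(κ) = coth κ − 1/κ,
⟨R⟩ = λ(1−σ^Ns)/(1−σ), P = −λ/ln σ.

Wild-type defaults are the study conditions: N_A = 25000 (N = 55764
polymers, ~1.0M segments), ε = 0.5, κ = 18. Growth is vectorized across
polymers; one full realization takes a few seconds.

## Motor-velocity field and bias statistics

Segments are binned by midpoint on a cubic grid of spacing dG = 0.04;
per-cell *vector sums* of unit orientations form the motor field, globally
scaled so the mean magnitude over occupied cells is 1. The sum convention
(not the per-cell mean) is the one consistent with the flow calibration
below; per-cell counts give the density map.

Directional bias conventions (both reported): the posterior share P% of
segments with positive AP component, its excess over parity P−50 (the
"x% more posterior than anterior" figure; wild type ≈ 8.5), and the
difference P−(100−P). A mid-plane slab one cell thick gives the 2D
statistic (wild type ≈ 60.6% posterior); `bias_vs_depth` sweeps the slab
from the lateral cortex to the mid-plane. Segments with exactly zero axial
component are split evenly.

The temporal autocorrelation statistic
C(k) = ⟨(N−k)⁻¹ Σ_n u(n+k)·u(n)⟩, peak-normalized, quantifies the decay
of field sequences; tests verify AR(1) time-scale recovery within 10%.

## Stokes flow

Streaming is steady creeping flow (Re ≤ 2.5e−4 with worst-case cytoplasm
properties): −∇p + ∇²u + f = 0, ∇·u = 0, f = a′·v_m, no-slip on the
oocyte surface and optionally on a spherical nucleus (2.5% of the volume).
a′ = 45 (geometry-1; 55 for geometry-2) is the published coupling between
motor activity and force density.

Discretization: MAC staggered finite differences on the cell grid; the
curved wall is the staircase of interior cells. Velocity unknowns live on
faces between interior cell pairs; tangential wall neighbours use the
reflected ghost (wall at h/2), normal ones Dirichlet 0. The saddle system
is solved exactly via the pressure Schur complement (CG with sparse-LU
factorizations of the three component Laplacians, cached per
geometry/resolution and reused across ensembles). Discrete divergence
reaches round-off (~1e−9 of the velocity scale); uniform (hydrostatically
balanced) forcing yields u = 0 to 1e−8, and flows are exactly linear in
a′, which makes calibration a one-solve rescaling.

Speed statistics are volume-weighted quadratures of (1/V)∫|u| dV over the
smooth domain (per-cell inside fractions from 27-point subsampling), not
staircase cell averages. "2D cross-section" speeds are |u| in the
mid-sagittal plane; an in-plane-only variant mimics PIV. With the study
conditions and a′ = 45 a 10-field ensemble gives a 3D mean of ~15.1 nm/s
and a 2D mean of ~15.6 nm/s on our discretization (published FEM values:
14.5/14.8 nm/s), mesh-converged to ~2% between h = 0.08 and h = 0.04.

## Rod model and bifurcation analysis

The continuum counterpart treats MTs as straight rods nucleated on the
cortex with the same density and length law. The weight of a rod from σ
reaching x is p_Σ(s)·N(2πr²)⁻¹[1−Φ(r)] restricted to the inward half
space (n̂·ê_xσ ≥ 0); rods crossing the concave anterior outside the
volume are not excluded (an acknowledged approximation of the model).
The rod preset uses ε = 0.28: straight rods must be shorter than the
polymers' contour length to match their ~54% end-to-end reach.

Off-axis, the net orientation o(x) and density p_V(x) are computed by
product Gauss–Legendre (ρ, 128/cap) × trapezoid (φ, 256) quadrature with
a 1e−3 exclusion ball around x; a Monte-Carlo rod sampler serves as an
independent oracle. On the AP axis the azimuthal integral is analytic
(transverse components cancel), reducing each evaluation to a 1D
quadrature — this makes (ε, k_P) phase diagrams cheap.

Topology classification from the axial profile of o_z·p_V on 200 uniform
points offset 0.02 from the poles (half a coarse-grid cell, where the
discrete grids place their posterior-most sample; with a much smaller
offset the unstable fixed point formally never leaves the grid and the
single-attractor region of the phase diagram collapses):

* positive everywhere → wild type (everything flows posterior);
* negative somewhere, positive at the posterior-most point → split (a
  stable/unstable pair partitions the oocyte);
* negative at the posterior-most point → strong hypomorph (single
  attractor).

Sign changes are refined by bisection; +/− is stable, −/+ unstable. Near
the wildtype/split boundary the pair separation scales as the square root
of the distance to the boundary — the saddle-node signature, whose 2D
normal form v = (x²+λ, −y) is provided for reference.

## Cargo transport

Bound cargo (fraction β = 0.13 at equilibrium) advects with v_m; unbound
cargo advects with u and diffuses with Pe⁻¹; exchange at 2Da(βc_u−(1−β)c_b).
Dimensional anchors: k_u = 0.17 s⁻¹, k_b = 0.0255 s⁻¹, K = 0.09775 s⁻¹,
D = 0.02 µm²/s ⇒ Da = 9.775, Pe = 1250. Dynein cargo (*bicoid*) uses the
motor field with inverted sign. Scenarios with cytoskeletal transport off
set k_b = 0 (nothing enters the bound state). The anchored variant
replaces the bound state by an immobile species that binds irreversibly
(β_anch = 1, Da_anch = 12.75) only within 4 µm of the posterior pole.

Numerics: explicit, conservative first-order upwind finite volumes on the
staggered grid (face velocities are adjacent-cell averages; wall faces
carry zero flux). Mass is conserved to round-off; positivity holds under
the per-axis CFL check up to round-off-level undershoots near the bound.
Each (v_m, u) pair is active for 432 steps of dt = 0.005 (3.6 simulated
minutes); pairs cycle in seed-randomized order through a pre-computed
library, with total duration the controlling parameter (1 h = 36
nondimensional units). Motor and flow fields are always *computed* at
dG = 0.04 — the normalized field's amplitude depends on the binning
scale — and only then resampled to a coarser transport grid if one is
requested.

Initial conditions: the late-stage-8 *oskar* cloud is an isotropic
Gaussian (sd 0.15) at the domain centre; injections are Gaussians of sd
0.08 at named sites (posterior-centre, anterior-dorsal, anterior-middle);
conditioned-*bicoid* starts as a two-cell layer on the anterior surface.
Mass splits β:(1−β) between bound and unbound unless binding is off.

The posterior-slice readout is the mass fraction within 4 µm (0.08) of
the posterior pole along the axis. Reduced-scale runs (dG = 0.08–0.1,
dt scaled to keep 2.16 time units per pair, ensembles of ~10 pairs) keep
the full pipeline inside test budgets; the slice fractions at reduced
scale are resolution-sensitive at the tens-of-percent level, which the
acceptance tests treat as scaled-down reproductions, while the *ordering*
of scenarios and the qualitative localisation patterns are the robust
observables.

## What the synthetic conditions do not capture

The generator emulates the study conditions (cytoskeleton statistics,
field ensembles, scenario initial conditions); it does not model dynamic
instability over time, MT–MT interactions, nurse-cell inflow, anchoring
biology beyond the idealized posterior sink, or image-derived geometries.
Passing tests therefore demonstrate internal consistency of the models
and reproduction of the published summary statistics, not agreement with
any particular experimental oocyte.

## Known limitations

* The staircase wall is first-order accurate; absolute mean flow speeds
  carry a discretization bias of order +5% relative to the published
  FEM values with the published a′ = 45 (relative and qualitative flow
  properties are unaffected, and `calibrate_a_prime` recovers any target
  mean exactly by linearity). Near the posterior cone the flow structure
  differs more strongly from the published fields — our flows retain
  4–5 nm/s recirculation there — which inverts the sign of the (small)
  flow contribution to posterior cargo localisation and inflates the
  idealized anchor's capture rate relative to the published runs.
* First-order upwind advection adds numerical diffusion ~|v|h/2, which
  exceeds the physical Pe⁻¹; localisation magnitudes at the posterior
  slice are accordingly resolution-dependent (the published values used
  the same scheme class at dG = 0.04).
* The rod model's topology near the posterior pole depends on the
  posterior-most sampling offset (see above); we fix it at dG/2.
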