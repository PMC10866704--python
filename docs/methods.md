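# Methods

`fibrelax` is an agent-based model of type-1 collagen matrices built to
study how network architecture — individual fibrils versus bundled
fibrils — controls stress relaxation and, through it, matrix
viscoelasticity.  This note records the model, its assumptions, the
default parameters and why they were chosen, and what the synthetic
systems do and do not capture.

## Model

**Geometry.** The simulation box is rectangular (20 × 20 × 5 µm by
default) and periodic along x and z only.  The two boundaries normal to
y are physical walls: beads within a tolerance of a wall at assembly
time are permanently anchored to it.  Units are µm, s, pN throughout, so
a stress in pN/µm² is numerically a stress in Pa.

**Fibrils.** Each fibril is a chain of beads connected by cylindrical
segments of rest length `l0` (0.5 µm) and radius `r_f` (0.05 µm).
Elasticity is harmonic: axial stretching `E = ½κ_s(l−l0)²` per segment
and angular bending `E = ½κ_b φ²` at each interior bead.  Assembly
nucleates each fibril as a single segment at a random position and
orientation and elongates it segment by segment — with a small Gaussian
directional noise and reflection of the growth direction at the y-walls —
up to a 3 µm (or 5 µm) target, never depolymerizing.  The fibril count is
the smallest one whose fully elongated mass reaches the target
concentration of 3.65 mg/ml, computed from the specific volume of
collagen, 0.73 ml/g.

**Connectors.** Two kinds of two-site connectors join points on distinct
fibrils, both modeled as harmonic springs (`κ_c`) between arc-length
attachment points:

* *Crosslinkers* are transient.  Candidate attachment points are
  scattered uniformly along fibril arc length at a fixed density; each
  binds a partner fibril chosen uniformly among all others whose nearest
  point lies within the capture radius, attaching at that nearest point
  with rest length equal to the current separation (so new bonds are
  born unloaded).  Crossing angle plays no role in acceptance.  A bound
  crosslinker unbinds at the force-dependent Bell rate
  `k = k₀·exp(|F|·λ/k_BT)`, `F` being its instantaneous spring tension;
  an unbound one may rebind from its surviving attachment to the nearest
  in-range fibril point at a fixed rebinding rate.
* *Bundlers* are permanent.  In the long, tight-bundle matrix they tie
  groups of parallel, axially staggered fibrils together at regular arc
  intervals; in the short, loose-bundle matrix they join fibrils end to
  end into chains whose junction angle is exactly θ (azimuthally
  randomized).

**Dynamics.** Beads follow the overdamped Langevin equation integrated
with an explicit Euler scheme: `Δr = (F/ζ)Δt + √(2·k_BT_mech·Δt/ζ)·ξ`.
Anchored beads are excluded from the update; +y-wall anchors follow the
prescribed shear motion, −y anchors are fixed.  Bond kinetics are
evaluated every `kinetics_stride` steps (a τ-leap with kinetic timestep
`stride·Δt`, 5 ms by default), which keeps the rebinding
nearest-neighbour search affordable.

**Rheology protocol.** A run consists of (i) an equilibration phase at
zero strain, (ii) a linear ramp of the +y wall along x to an engineering
shear strain of 20% (displacement `γ·L_y`), and (iii) a hold during which
the boundary stress `σ = −(ΣF_x on +y anchors)/(L_x·L_z)` is recorded.
Stress is reported as its average over each sampling window rather than
an instantaneous value — a lock-in-style readout that suppresses thermal
force noise, whose correlation time (ζ/κ ≈ 1 ms) is far below the 50 ms
window.  The relaxation curve is normalized to the first window fully
inside the hold, and τ½ is the first crossing of ½, located by linear
interpolation after a light centered moving average (5 samples).  A run
may stop early once the normalized stress falls below a configurable
threshold.

## Parameters

The discretization and all mechanical/kinetic constants are not fixed by
any published table available to us, so the defaults below were chosen
once for physical plausibility at desktop scale and are fully
configurable.

| parameter | default | units | rationale |
|---|---|---|---|
| `l0`, `r_f` | 0.5, 0.05 | µm | 6 segments per 3 µm fibril; ~227 fibrils at 3.65 mg/ml |
| `κ_s` | 20 | pN/µm | soft enough for Δt = 10⁻⁴ s; stiff enough that segment strain stays ≲20% under the 20% protocol |
| `κ_b` | 2 | pN·µm/rad² | persistence length κ_b·l0/k_BT ≈ 230 µm ≫ fibril length: fibrils are nearly straight, as real collagen fibrils are |
| `κ_c` | 5 | pN/µm | beads can carry several connectors; keeps the summed local stiffness inside the integrator's stability margin |
| `k₀` | 0.1 | 1/s | unloaded bond lifetime 10 s, inside the 60 s observation window |
| `λ` | 0.01 | µm | Bell force scale k_BT/λ ≈ 0.43 pN sits in the upper tail (≈99th percentile) of the simulated bond-tension distribution, so the most-loaded bonds unbind orders of magnitude faster than the unloaded bulk |
| `k_BT` | 4.28×10⁻³ | pN·µm | 310 K; enters the Bell rate |
| `k_BT_mech` | = k_BT (0 in rheology runs) | pN·µm | see below |
| `ζ` | 0.01 | pN·s/µm | mechanical mode times ζ/κ ~ 1 ms–0.5 s, resolvable and fast |
| `Δt` | 10⁻⁴ | s | within the enforced bound Δt ≤ 0.25·ζ/max(κ_s, κ_c); trajectories match Δt = 5×10⁻⁵ runs |
| capture radius | 1.5 | µm | smallest value at which the crosslink graph of the default matrix percolates between the y-walls with mean fibril degree > 2 |
| crosslinker density | 4 | 1/µm | with the capture radius, mean degree ≈ 6–7 |
| rebind rate | 1 | 1/s | 10·k₀: a sheared network stays connected over the hold instead of fluidizing irreversibly |

**Two temperatures.** The coarse bead-spring fibril is many orders of
magnitude softer than a real collagen fibril (which is nearly athermal at
these scales), so driving the beads with the full 310 K noise grossly
exaggerates entropic creep: in early experiments a *permanently*
crosslinked network lost half its stress to thermal annealing, masking
bond-kinetic relaxation entirely.  `k_BT` in Bell's law is a molecular
bond property and keeps its physical value; the bead-noise temperature
`k_BT_mech` defaults to the same value for generic dynamics but is set to
0 in the rheology protocols, whose relaxation is then driven purely by
bond kinetics (plus stochastic assembly).  The thermal machinery is fully
implemented and validated (diffusion, moment tests).

**Quasi-static loading.** The default 5 s ramp is slow compared with the
network's slowest mechanical modes (~0.3 s), so the hold starts near the
relaxed elastic stress: with permanent crosslinkers the normalized stress
holds a flat plateau (machine-flat late in the hold), and any decay under
transient crosslinkers is attributable to bond turnover.

## Profiles and problem sizes

Two named profiles are shipped.  `paper` is the full 20 × 20 × 5 µm box
(~227 fibrils, ~1600 beads).  `desk` is a 12 × 12 × 3 µm box (~49
fibrils), with a thicker anchoring layer (1.5 µm) so that whole-chain
placements reliably touch both walls, and 3 fibrils per loose-bundle
chain so chains fit the box; it is the profile used by the test suite and
the structure–function comparisons, where each condition is repeated over
5 independent seeds.  Runs of 60 s simulated hold take tens of seconds
each at desk scale.

## What the synthetic systems show — and what they do not

The matrices are geometric constructions, not outcomes of
diffusion-limited self-assembly; fibril lengths are uniform, not
distributed; crosslinker placement knows nothing about excluded volume;
and the capture radius needed for percolation of 0.05 µm-radius fibrils
at 3.65 mg/ml (1.5 µm) is far larger than a molecular binder, so each
"crosslinker" should be read as a coarse-grained cluster of weak bonds.
Passing the directional tests therefore says the *mechanistic chain*
(architecture → load distribution → Bell kinetics → relaxation) operates
in the model; it does not make the curves quantitatively comparable to
any instrument record.

Two of the three relaxation orderings reproduce robustly at desk scale:
shorter loose-bundle constituents relax faster (L_B = 1.5 vs 3 µm at
θ = 0°), and smaller junction angles relax faster (θ = 0° vs 30° at
L_B = 3 µm), as does the structural ordering (bundled matrices have
higher per-cell mass heterogeneity than fibrillar ones at matched
concentration).  The comparison between the loose-bundle and fibrillar
architectures is a known limitation of this parameterization: end-to-end
bundling replaces two-thirds of a chain's junctions with permanent
bundlers and *adds* graph connectivity at the junctions, so bundled
networks here carry load through fewer transient bonds in series while
their bond-tension distributions are statistically indistinguishable from
the fibrillar ones — and they consequently relax more slowly, not faster.
Reproducing a faster bundled relaxation appears to require a structural
regime (thicker fibrils, short-range contact binding, bundling-induced
crosslink depletion) that a thin-fibril desk-scale model cannot reach
while still percolating.  The acceptance test states the expected
ordering faithfully and is allowed to fail on this sub-claim.

## Numerical choices and degenerate inputs

* Minimum-image displacements are used for every geometric quantity; the
  x/z fold maps to (−L/2, L/2].  Anchored beads are never re-wrapped, so
  wall displacement is well defined.
* The bending force uses the standard angle-potential gradient with a
  guarded sin φ denominator; forces match −∇E to ≤10⁻⁶ relative error by
  central differences.
* Connector attachments are material (rest-length) arc coordinates, so
  attachments ride their material point as segments strain.
* A connector whose endpoints coincide (chain junctions, rest length 0)
  exerts no force below a 10⁻¹² µm separation guard.
* Zero-length segments are rejected as corrupt states; non-finite forces
  abort a run with an error rather than propagating.
* τ½ is censored (`None`) when the normalized stress never reaches ½;
  sweep tables count censored replicates separately and flag rows where
  every replicate is censored.
* Assembly rejects target lengths that are not whole multiples of `l0`,
  keeping segment rest lengths uniform.

## Instrument analytics

The `mechlab` module implements the bench-side analyses: a Hertz
spherical-indentation fit `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}` with a
grid-searched contact point (ν defaults to 0.5, incompressible soft
tissue; tip radius 2.5 µm for a 5 µm sphere); trapezoidal hysteresis area
between loading and unloading branches; the loss tangent G″/G′; and
circularity 4πA/P².  Synthetic generators provide Kelvin–Voigt-augmented
Hertz force curves and Prony-series relaxation records with embedded
ground truth (the half-life root-found with Brent's method); estimator
recovery is tested on noiseless and noisy records.
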