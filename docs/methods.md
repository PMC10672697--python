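# Methods

## Model

Trabecular bone adaptation is modeled as an interface-evolution problem.
The bone surface is the zero level of an embedding φ (signed distance,
micrometres, negative inside bone) evolving under the level-set equation

    φ_t + F |∇φ| = 0,     F = a − b κ,

where `a` (μm/day) is a spatially uniform advection speed — net formation
when positive, net resorption when negative — and `b` (μm²/day) weights the
local mean curvature κ = div(∇φ/|∇φ|) (sum of principal curvatures; 2/R for
a sphere of radius R, positive on convex bone). The curvature term
preferentially erodes thin, highly curved struts, the geometric signature
proposed for age-related (and microgravity-accelerated) trabecular bone
loss. All internal units are micrometres and days; voxel volumes are
isotropic (default spacing 61 μm, the resolution of second-generation
HR-pQCT).

The inverse problem identifies the participant-specific pair θ = (a, b)
from two co-registered binary volumes and the elapsed days, by minimizing
the non-overlap cost

    J(θ) = |predict(θ) XOR target| / |target bone|,

where `predict(θ)` forward-evolves the baseline for the full interval.

## Discretization

* Forward Euler in time; Godunov upwinding for the advection term; central
  second-order differences for the parabolic curvature term, which is
  applied as b·κ·|∇φ| (true mean-curvature motion of all level sets).
* Stable step: dt = CFL / (3|a|/h + 6b/h²), CFL default 0.5; the final
  partial step lands exactly on the requested day count.
* κ is clamped to ±1/h: a one-voxel sphere is the finest resolvable
  feature, and unresolved sub-voxel curvature otherwise produces unstable
  speeds. Voxels with |∇φ| < 1e-8 get κ = 0.
* Replicate-edge (zero-gradient) padding everywhere: the analyzed region is
  an interior volume of interest, so no-flux is the least-biased boundary.
* Full-grid updates (no narrow band): at desk scale (≤ 96³ voxels) the
  simple scheme is affordable and easier to verify. The hot stencils have
  fused single-pass kernels (numba) that are bitwise-equivalent to the
  reference numpy implementations (asserted by a test); the numpy path is
  the fallback.

### Signed distances and the half-voxel convention

Distances are voxel-center to voxel-center (scipy Euclidean distance
transform): a bone voxel face-adjacent to background has φ = −h, and the
zero level lies between voxel centers. Two consequences are accepted and
compensated where they matter:

* |φ| overestimates the true distance to the surface by about h/2 on each
  side; across the interface the jump is 2h, so the central difference in
  the adjacent voxel layer is 1.5, not 1. Tests of the Eikonal property
  exclude that layer (and medial-axis shocks, where central differences
  legitimately collapse).
* When differencing two embeddings (inverse-solver initialization), the
  half-voxel offsets cancel for voxels that keep their phase but *add* for
  voxels that flip phase, biasing observed speeds by a full voxel there.
  Both embeddings are therefore corrected by φ − sign(φ)·h/2 before
  differencing (measured: bias on a pure-advection sphere oracle drops from
  ~28% to ~2%).

### Reinitialization

Repeated evolution degrades the unit-gradient property the curvature
stencil assumes, so the embedding is reinitialized every 20 steps
(configurable) by relaxing φ_τ = sign(φ₀)(1 − |∇φ|) with Godunov upwinding
and a subcell interface anchor (the Russo–Smereka fix): interface voxels
relax toward φ₀/|∇φ₀|, their first-order sub-voxel distance. Voxels already
within 8% of unit gradient are left untouched, which makes an exact signed
distance field a true fixed point (idempotence to 0.1 μm in the band) and
preserves the voxel sign pattern — binary extraction is unchanged by
construction. Fifteen sweeps at Δτ = h/2 clean ~7 voxel layers around the
surface, ample for the 3-voxel band the stencils read.

## Inverse solver

Parameters are normalized by s_a = h/T and s_b = h²/T (h voxel spacing, T
interval days), making the optimizer hyper-parameters dimensionless and
transferable across voxel sizes and scan intervals. Defaults follow the
in vivo protocol this pipeline mirrors: Adam learning rate η = 5×10⁻⁵,
b-gradient scaling γ = 5×10⁻⁴, convergence tolerance 10⁻⁸ on the normalized
parameter-step norm, 4000-iteration cap, and rejection of fits whose
prediction lies farther than one voxel (mean symmetric surface distance
> h) from the fitted scan.

### Initialization

1. **Linear least squares.** On the baseline surface band (|φ₀| ≤ 2h) the
   observed normal speed is F̂ = −(φ₁ − φ₀)/T (with the half-voxel
   correction above); OLS of F̂ on [1, −κ(φ₀)] gives (a₀, b₀).
2. **Staged refinement.** The single-step linearization degrades badly once
   the surface moves more than a voxel or thin struts vanish within the
   interval (the curvature term is runaway: κ grows as struts thin). Since
   Adam's step budget (η × max_iter ≈ 0.2 normalized units) cannot rescue a
   distant start, the start is refined on the band-embedding residual
   (evaluated on the union of both scans' 2h-bands, so sensitivity survives
   large surface motion): a coarse grid over b — the weakly identified,
   strongly nonlinear direction — with a nested secant solve for a at each
   node (the mean signed band residual is monotone in a), early-stopped
   once clearly past the rms minimum, then two bisection rounds and a
   parabolic step on rms²(b). Every stage is a sequence of 1-D linear
   solves, robust where joint Newton-type steps follow a curved valley.
   Measured on 64³ pairs over the full b ∈ [0, 600] range: a recovered
   within ~6%, b near-exactly; without the stage, fits started 4× off.

### Adam stage and convergence

Central finite differences on the 2-parameter space (4 simulations per
gradient, step 0.05 of each scale — wide enough to straddle the staircase
plateaus of the integer XOR count), with the b-component of the gradient
scaled by γ before the update. Note that Adam's per-component normalization
makes a pure gradient rescaling nearly a no-op; γ is kept in its stated
role and isolated in one line for easy revision.

Cost evaluations are memoized on a quantized parameter grid (0.002 of
scale for the cost trace, 0.01 for gradient probes). The XOR cost is
piecewise constant at far finer granularity than η moves per iteration, so
the quantization is lossless at the resolution the optimizer can sense; it
is what makes 4000-iteration fits affordable.

Convergence is declared when the normalized parameter step falls below the
tolerance, or when the best cost has not improved by at least one
target-voxel equivalent over a 100-iteration window — the iterate is then
trapped on a staircase plateau or limit cycle around a stationary point
(Adam's step size does not vanish in a limit cycle, so the norm criterion
alone can fail to fire at a perfectly identified optimum). Fits still
descending at the iteration cap are reported non-converged — a tabulated
outcome, never an exception. The returned parameters are the best-cost
iterate; b < 0 (backward diffusion) is flagged, and projections onto b ≥ 0
are used inside cost evaluations.

## Morphometry

* **Static**: Tb.BV/TV (%) by voxel counting over the mask; Tb.Th and Tb.Sp
  (mm) as the mean sphere-fitting (Hildebrand–Rüegsegger) local thickness
  of bone and background; Tb.N (1/mm) by the mid-axis method — the inverse
  mean sphere-fitting thickness of the non-skeleton phase (skeletonization
  via scikit-image) — with an `inverse-sum` variant 1/(Tb.Th + Tb.Sp)
  available because scanner implementations differ.
* **Local thickness** is computed by a descending-radius sweep of the
  distance map (radii binned at 0.5 voxel, the method's placement
  resolution): voxels reaching radius r seed spheres that stamp diameter 2r
  onto uncovered voxels.
* **Overlays** code each voxel as background / resorbed (baseline only) /
  formed (follow-up only) / quiescent (both). **Dynamic morphometry**: BFR
  (BRR) = formed (resorbed) volume per baseline bone volume per day, %/day;
  MAR (MRR) = mean sphere-fitting thickness of the formed (resorbed) set
  per day, μm/day; MS (ES) = formed (eroded) fraction of the bone surface,
  %, with the surface taken from the *union* volume — the only surface set
  containing both formed and resorbed voxels (a baseline-only or
  follow-up-only surface would structurally miss one of the two). Empty
  formed/resorbed sets give 0 with a flag rather than NaN, keeping cohort
  tables total.
* **Agreement**: Dice 2|A∩B|/(|A|+|B|); mean symmetric surface distance in
  μm (surface = bone voxels with a face-adjacent background voxel; mean of
  both directed mean distances). Mean — not RMS or Hausdorff — is used for
  the symmetric distance; 26-connectivity for components, 6-connectivity
  for surfaces.

## Synthetic data

No in vivo volumes are distributed with the package, so study conditions
are emulated:

* **GRF structures**: white noise convolved (periodically) with a Gaussian
  of σ = correlation_length/2 voxels, thresholded at the quantile giving
  the target BV/TV, largest connected component kept under *periodic*
  26-connectivity (matching the wrap-convolved field; plain connectivity
  sheds boundary fragments from small volumes). Defaults: BV/TV 25%
  (connected GRF structures need > ~22%, slightly above typical tibial
  values), correlation length 260 μm (puts mean strut thickness within a
  factor of two of the ~265 μm reported for the population of interest).
* **Cohorts**: 16 participants × 2 sites × time points L, R+0, R+6, R+12
  at intervals of 180/182/183 days (approximately six months). Per-interval
  true parameters are drawn as interval mean + participant random effect +
  interval-level noise; interval means for a are −0.264/−0.243/−0.238
  μm/day (the reported median adaptation rates of roughly −96/−89/−87
  μm/year), with b centered at 30 μm²/day so the curvature term contributes
  at the same order on 260 μm-scale struts. Between-participant variance
  (SD 0.04 μm/day on a, 10 μm²/day on b) exists so participant-specific
  fitting is meaningful.
* **Noise** (optional, off by default) flips surface-band voxels at a given
  rate — emulating segmentation/registration jitter — followed by removal
  of components under 30 voxels (specks). Larger fragments a flip may sever
  are kept: amputating them would perturb the volume an order of magnitude
  more than the noise itself.
* Everything is bitwise-reproducible for a fixed seed.

What the synthetic cohort does *not* emulate: scanner noise and beam
hardening, motion artifacts, registration error beyond band jitter,
cortical bone, and real trabecular topology (plate/rod mixtures,
anisotropy). Passing tests therefore demonstrate the *method* — solver
correctness, parameter identifiability, pipeline bookkeeping — not
clinical accuracy on real scans.

## Experiments

The short-term experiment fits each consecutive scan pair and forward-
predicts that interval's endpoint; the long-term experiment fits only the
first recovery interval (R+0→R+6) and extrapolates from R+0 over the exact
R+0→R+12 day count, judging convergence (and the one-voxel rejection rule)
at R+6 and accuracy at R+12. Exclusions (non-converged, distance-rejected,
failed) are tabulated and always satisfy analyzed + excluded = total.
Summary statistics are those with closed forms: absolute percent errors
(mean ± SD), medians with quartiles for dynamic morphometry and agreement
metrics, Bland–Altman bias and 1.96·SD limits, OLS slope/intercept/R², and
paired t-tests. Linear mixed-effects modeling is deliberately delegated to
external statistics software operating on the exported record tables.

## Problem sizes

Defaults target desk-scale runs: unit tests use 32³–52³ phantoms; the
parameter-recovery experiment uses 64³ structures over 45–60-day intervals
(the staged initializer's accuracy is insensitive to the interval once the
displacement signal exceeds the sub-voxel regime); the end-to-end cohort
runs at the full 16 × 2 × 3 design with 32³ volumes (`reduced_spec`). The
full 96³ default of `CohortSpec` is intended for overnight runs.

## Known limitations

* b is weakly identified when band curvature variance is low (near-planar
  structures); the fit reports that variance as a diagnostic.
* Relative error on a is meaningless as |a| → 0 (cohort medians are the
  robust summary).
* The placement of the zero level between voxel centers caps agreement
  metrics: sub-voxel surface positions are not represented, so symmetric
  distances below ~h/2 are not meaningful differences.
* The forward model is deterministic and purely geometric; biological
  stochasticity and load adaptation are out of scope (the speed-function
  interface is the extension point).
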