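# Methods

## Model

A tracer load map σ(r) ≥ 0 is treated as an electrical conductivity
and the injection voxel r₀ as a unit current source. The potential φ
solves the screened Poisson problem

    (−∇·(σ̃ ∇) + α) φ = δ(r − r₀),     σ̃ = σ + σ_floor,

with homogeneous Neumann (zero-flux) boundaries, and the tracked
quantity is the flux j = σ̃ ∇φ oriented away from the injection. The
screening term αφ is a distributed leak: it absorbs the injected
current throughout the volume, makes the operator strictly positive
definite, and gives φ the exponential decay length √(σ̃/α) (the Green's
function on uniform conductivity is the Yukawa kernel
e^{−κr}/(4πσr), κ = √(α/σ)).

**Sign convention.** The equation is sometimes written as
∇·(σ∇φ) + αφ − δ = 0 with j = σ∇φ; taken literally that operator is
negative (semi)definite and its flux points toward the source. We solve
the equivalent SPD form above and orient the flux away from the
injection (φ peaks at the source, so the flux runs along −∇φ). The
streamline geometry is identical; the solver is well posed.

**Physical reading of the flux.** Integral curves of j are current
field lines of a leaky conductor. Because current leaks continuously
through the tube wall, off-axis field lines gradually peel outward;
this is a property of the model, not a numerical artifact, and it
bounds how tightly tracks can hug a tube over long distances (see
"Phantom recovery" below).

## Discretization and solver

- Conservative 7-point finite-volume stencil on the voxel grid, face
  conductivity = harmonic mean of the two adjacent σ̃ (correct flux
  continuity across conductivity jumps). Applied to a constant c the
  operator returns αc exactly, so the discrete conservation law
  α·Σφ = 1 holds to solver precision for a unit source.
- Matrix-free application; conjugate gradients with Jacobi
  preconditioning, relative residual tolerance 1e-8 (configurable),
  failure to converge raises with the achieved residual.
- `sigma_floor` defaults to 1e-4·max(σ): keeps the operator irreducible
  where tracer is absent. `alpha` defaults to mean(σ̃)/100, i.e. a
  decay length of ~10 voxels; both are exposed in
  `ScreenedPoissonConfig` and the right α is problem-dependent (a decay
  length comparable to the expected tract length carries current to the
  distal end).
- Flux: central differences in the interior, one-sided at the
  boundary, then the boundary-normal component is forced to zero
  (Neumann contract). Units are voxel units throughout (h = 1); with
  physical spacing h the voxel-unit solve uses α_vox = α_phys·h² and
  returns φ_vox = h·φ_phys.

## Streamline tracking

Unit-speed 4th-order Runge–Kutta on the trilinearly interpolated and
then normalized flux direction: the flux magnitude decays like ~1/r²
from the source, so magnitude-weighted integration would stall while
the direction stays well defined. Tracking is unidirectional (away
from the source; anterograde tracing defines a corticofugal
direction), and φ strictly decreases along every track.

Stopping rules: leaving the grid, `max_steps`, or local |j| falling
below `min_flux_frac` × |j| at the streamline's own seed. The default
`min_flux_frac` is 0.05: crossing a tube's Gaussian wall drops |j| by
one to two orders of magnitude within a couple of voxels, while the
along-tube decay over desk-scale tract lengths stays above ~0.2 of the
seed value, so a few-percent threshold separates in-tube from
background. (A much smaller threshold lets tracks overshoot the distal
end by the length of the tube's own Gaussian tail — several voxels —
before stopping.) The seed-relative reference means seeds placed inside
the ~1/r² singularity at the source stop almost immediately; seeds
belong in the injection core a few voxels downstream. No curvature
criterion is applied by default: the flux of an elliptic problem is
smooth.

Seeding strategies: `injection_sphere` (uniform in a 2-voxel ball
around the injection) and `sigma_percentile` (uniform over voxels above
the 90th σ percentile). Both are deterministic given the seed.

## Connectivity matrices and balancing

- Tracer route: each injection volume is divided by its Euclidean (L2)
  norm (removing absolute intensity differences), volumes are summed
  voxel-wise within each cortical injection group ("sum image"; no
  division by group size — subsequent balancing removes gross row
  scale), and the mean sum-image signal over each target parcel mask is
  the raw connection strength. A row's own parcel is excluded when the
  targets are cortical (association matrix).
- Streamline route: a streamline traverses a parcel iff ≥1 of its
  points, mapped through the atlas affine and rounded to the nearest
  voxel, carries that label; entry (a,b) counts streamlines traversing
  both. Nearest-voxel lookup matches common connectome practice at
  step sizes ≤1 voxel; no segment–voxel intersection test.
- Sinkhorn–Knopp: alternating row/column scaling. Square matrices
  converge to the doubly stochastic form; for an r×c rectangular matrix
  the targets are row sums 1 and column sums r/c (total mass r,
  reducing to the square case at r=c). Default tolerance 1e-10 on the
  worst marginal. Zero rows/columns are rejected rather than ε-padded:
  scaling cannot repair absent connectivity, and padding would
  fabricate it.

## Group statistics

Per-edge classical pooled-variance two-sample t-tests (Welch behind a
flag), Bonferroni correction over the tested edge family (default: all
edges of the matrix), significance at adjusted p < 0.05; raw and
adjusted p are both reported since borderline effects are
conventionally shown before and after correction. Edges with zero
variance in both groups get a NaN t-value and an explicit flag instead
of ±∞ or silent dropping — the case arises in noise-free synthetic
data. Sub-network aggregation sums a balanced matrix over the member
edges of the affect (AN), cognitive-motor-control (CMCN) and
reward/maintenance (RMN) rosters, restricted to parcels the toy roster
carries (mediodorsal thalamus → MD, SNr → SN, ventrolateral thalamus →
VL; amygdala, hippocampus, accumbens, caudate and insula have no
stand-in and are dropped). The default-mode network is excluded: it
extends outside the prefrontal cortex.

## Synthetic data: what it emulates, and what not

All generators return the latent truth alongside the data and are
bit-deterministic given their seed.

- **Tube phantoms**: σ = background + Σ_k w_k·peak·exp(−d_k²/2r²) +
  clipped Gaussian noise, d_k the distance to centerline k. The smooth
  Gaussian profile avoids discretization artifacts in the PDE; noise is
  additive (not Poisson) because the pipeline assumes only
  nonnegativity.
- **Toy atlas** (48³ by default, ≥42 per axis): seven 7³ cortical
  blocks at grid corners (margin 5) and six subcortical parcels at ±7
  voxels from the center — 5³ blocks except the VTA, a radius-2 sphere
  mirroring its coordinate-sphere definition. All parcels disjoint,
  label 0 background.
- **Planted tractograms**: per parcel pair, exactly the requested
  number of polylines, each verified to visit only the two parcels
  (quadratic-Bezier midpoint jitter, re-drawn until the label contract
  holds), so traversal counting recovers the count matrix exactly.
- **Injection cohorts**: default roster 6/29/2/3/3/3/5 injections for
  OFC/dlPFC/vlPFC/dmPFC/dACC/vACC/premotor (51 volumes). Each
  injection branches from a random source voxel of its parcel to all
  six subcortical targets. Branch weights per parcel are a random
  permutation of the ladder 1,2,4,8,16,32: the factor-2 spacing
  dominates the geometry-factor difference between cube and sphere
  masks (~1.8×), so the planted ordering is recoverable from raw mean
  signals. Tube radius 1.0 and clearance-verified routing (mid-waypoint
  pushed outward until the centerline stays ≥4 voxels from every
  non-target mask) keep cross-branch contamination below ~2% of an
  on-target signal; without the clearance check a corridor to a
  far-side target can graze an intervening mask and invert adjacent
  ranks.
- **Two-group cohorts**: per-subject matrices = balanced baseline +
  i.i.d. N(0, sd²) per edge (clipped at 0; with baseline entries ~1/6
  and sd 0.02 clipping never triggers), patient group + δ at the effect
  edge; 12 subjects per group by default. No inter-edge correlation —
  the simplest structure satisfying the t-test's assumptions.

None of this emulates real anatomy (no hemispheres, white-matter
geometry, partial voluming, distance-dependent tractography bias, or
registration error). Passing tests therefore demonstrate correctness
of the algorithms under their own assumptions, not performance on
marmoset or human data.

## Study sizes used by the tests and acceptance script

Grids 48³–96³; 96³ for the Yukawa closed-form check (shells r∈[5,15]
voxels, α=0.01); the curved-tube recovery uses a quarter-arc of radius
30 on 48³ with α=1e-5 (decay length ≈ tube length), 50 seeds in a
radius-0.75 ball ~5 voxels down the centerline, steps 0.5 and 0.25.
Counting exactness: 50 planted 7×6 matrices with entries 0–5.
Calibration: 200 null cohorts (FWE) and 100 effect cohorts (δ = 4·sd).
The endpoint-recovery figure is the bundle terminal point (centroid of
streamline endpoints): individual endpoints scatter laterally by the
physical leak current, the centroid cancels that scatter and measures
where the reconstructed pathway terminates.

## Known limitations

- The α that best carries current to a tract's end depends on tract
  length; the package exposes it rather than estimating it.
- Direction-following tracks on a leaky conductor drift outward over
  long thin tubes (see above); seeding outside the tube core follows
  the physically real lateral leak and leaves immediately.
- Rectangular "doubly stochastic" balancing is a convention (rows 1,
  columns r/c); other marginal targets are equally defensible.
- The Bonferroni family is the set of edges passed to one call; users
  comparing several matrix types or hemispheres must decide the family
  themselves.
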