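# Methods

## Model and procedure

`lpadapt` treats design centering and volume estimation as two regimes of
one adaptive sampling process. The proposal is the uniform distribution on
an affine image of the unit Lp-ball,

    x = m + r · C s,    ||s||_p ≤ 1,    det C = 1,

parameterized by mean m ∈ ℝⁿ, radius r > 0, a unit-determinant
lower-triangular shape factor C, and the ball exponent p (p = ∞ is a
dedicated sentinel meaning the supremum norm; no formula approximates it
with a large finite p, which would overflow Γ(1 + n/p)).

Uniform ball samples use the generalized-Gamma construction: coordinates
are sign-symmetric with |·|^p ~ Gamma(1/p, 1), normalized to the unit
p-sphere, then scaled by u^(1/n), u ~ U(0,1). This is exact for every
p > 0, including the sub-additive quasi-norm range p < 1.

Each iteration draws λ candidates, queries the membership oracle for each,
and updates:

* **radius, per sample** — ×f_e = 1 + β(1−P) on a hit, ×f_c = f_e^(−P/(1−P))
  on a miss, so E[Δ log r] = 0 exactly at hit rate P. Radius control is the
  fastest feedback loop, hence per-sample; shape and mean need several
  points, hence per-batch. (Whether the radius reacts per sample or per
  batch is an open choice; per-sample was selected for feedback speed.)
* **empirical hitting probability, per sample** — EWMA of the hit indicator
  with effective memory M, initialized at the target P.
* **mean, per batch** — m ← (1−η_m) m + η_m · mean(feasible points); frozen
  when a batch has no feasible point.
* **shape, per batch** — with d_k = (x_k − m)/(r √m₂) the feasible
  displacements normalized by the radius *and* by the unit ball's
  per-coordinate second moment m₂(n, p) (1/(n+2) at p = 2, 1/3 at p = ∞),
  the covariance is relaxed toward their uniformly weighted scatter,
  C Cᵀ ← (1−η_C) C Cᵀ + η_C Σ w_k d_k d_kᵀ, refactored (lower Cholesky) and
  renormalized to det 1. The m₂ normalization makes an unconstrained batch
  leave the shape stationary in expectation; without it the effective
  shape-learning rate silently carries a 1/(n+2) factor. Log-linear
  recombination weights are available but uniform is the default.

The instantaneous volume estimate is V̂ = P_emp · rⁿ · vol(unit Lp-ball):
the overlap fraction times the proposal volume, an estimate of
vol(proposal ∩ A), which approaches vol(A) from below once the proposal
encloses the region. The population size λ is held fixed within a run.

## Hitting-probability schedules

Both tasks start at the information-theoretically motivated P = 0.35 ≈ 1/e.

* **Volume mode** lowers P through (0.35, 0.15, 0.06, 0.03, 0.01) so the
  proposal swells past the region boundary; the final volume is the mean of
  the instantaneous estimates over the last window (default: the last
  quarter of the final phase; an absolute count, e.g. 600 of 2,500, can be
  given). Averaging instantaneous estimates — rather than re-estimating
  from pooled samples — matches the stationary-process interpretation of
  the trace.
* **Centering mode** raises P through (0.35, 0.55, 0.75, 0.90), squeezing
  the proposal into the region; the center is the proposal mean averaged
  over the final window, and is verified against the oracle (in strongly
  non-convex regions an averaged mean can land outside A; the report
  records the verdict). Pushing P much closer to 1 is counterproductive: a
  near-1 target shrinks the proposal until almost every sample is feasible
  anywhere inside the region, which removes the restoring force that
  centers the mean.

A phase ends when its budget share is exhausted or when it is stationary:
the smoothed hitting probability has settled to within 25% of its target
*and* two consecutive non-overlapping windows of the volume estimate agree
within 2% (both thresholds configurable). Stationarity windows span at
least one smoothing memory, a phase must run at least four memories before
it may exit, and per-phase means are computed over the stationary tail —
all because the re-equilibration transient after a target switch lasts on
the order of one memory and is systematically biased (see below). The final
phase absorbs unused budget and always runs to completion so the averaging
window is well defined.

## Parameter defaults

| parameter | symbol | default | rationale |
|---|---|---|---|
| population size | λ | 4 + ⌊3 ln n⌋ | evolution-strategy convention |
| mean learning rate | η_m | 1/e ≈ 0.368 | Gaussian-Adaptation convention |
| covariance learning rate | η_C | 0.2/n | see below |
| radius gain | β | 0.08/n | see below |
| hit-smoothing memory | M | 40 n samples | see below |
| target P (initial) | P | 0.35 | ≈ 1/e, maximum-entropy optimum for convex regions |
| MVEE duality gap | — | 1e−7 (1e−4 as run diagnostic) | volume error ≪ statistical error |
| bound-point thinning cap | — | 5,000 points | MVEE cost grows with point count |

Units: all learning rates are per batch, β and 1/M per oracle evaluation;
r and m inherit the design-space units of the oracle.

The three non-conventional defaults come from an explicit bias/speed
analysis of the volume estimator. At stationarity the log-volume of the
proposal performs a mean-reverting random walk with per-hit impulse
n·log f_e ≈ nβ and reversion rate ≈ nβP per sample, giving stationary
log-volume variance ≈ nβ(1−P)/2. Because the same hit sequence drives both
the radius and the hitting-probability EWMA, E[P_emp · vol] exceeds the
true overlap by approximately

    nβ [ (1−P) α/(α+nβP) + (1−P)/4 ],   α = 1/M.

Three consequences: (i) β must scale as 1/n, or the bias grows with
dimension (β = 0.08/n holds it at 3–5% in every n tested); (ii) M must be
large against the radius-reversion time 1/(nβP) — the drivers therefore
raise the per-phase memory to max(40n, 1/(nβP)) as P decreases, and a
low-P phase needs a budget of several such memories to equilibrate (the
driver warns when it does not get one); (iii) η_C = 0.2/n is fast enough
to learn a √1000 axis-ratio region in 20-D within ~6×10⁴ evaluations —
rates ∝ 1/n² provably are not — while staying below the level where
low-rank scatter noise degrades coverage of pointed bodies (L1 balls).

## Geometric bounds

The minimum-volume enclosing (Loewner) ellipsoid of the feasible samples is
computed by Khachiyan's first-order reweighting with Sherman–Morrison
incremental updates, a convex-hull pre-reduction for n ≤ 6, an iteration
cap of 10⁵ (cap hit ⇒ warning plus best-so-far), and a final inflation by
the achieved duality gap so the containment contract holds even at early
stopping. Rank-deficient point sets raise an error naming the deficient
directions. The axis-aligned bounding box is the product of coordinate
extents. Both are computed on a thinned subsample (≤ 5,000 points) and in
log-space. While the Loewner volume still grows over a run, new parts of
the feasible region are still being discovered.

## Built-in regions and the fixture generator

The 2-D benchmarks (Storn rectangle-plus-arm, area exactly 101.0; Handle,
x⁶+y⁶−1.925x³y³ ≤ 1; Folium, −(x²+y²)³+4x²y² ≥ 0) are closed regions —
every defining inequality is non-strict. The Handle's area is computed by
quadrature of its polar radius (the polar form is smooth and strictly
positive); the Folium's area is π/2 exactly. Brute-force rejection boxes
are [0,10]×[−10,10], [−1.6,1.6]² and [−1.1,1.1]² respectively; both curved
bodies provably fit their boxes.

The fixture generator produces randomly rotated, log-spaced-anisotropic
Lp-ball regions with exact volumes attached, and the 20-D benchmark region
has log-spaced semi-axes with the longest √1000 times the shortest. These
fixtures emulate what matters to the sampler — anisotropy, orientation,
curvature of an Lp-boundary, known ground truth — but not everything real
oracles have: they are noise-free, deterministic, connected, star-shaped
about a known interior point, and cost microseconds per call. Passing
tests on them demonstrates correct geometry, adaptation and estimator
behavior; it does not demonstrate performance on disconnected regions or
on oracles whose answers are themselves noisy. The trajectory-band oracle
(`band_spec_oracle`) represents specification-style cases — a response
curve that must stay inside an envelope — with non-finite responses mapped
to "infeasible" rather than an exception.

## Problem sizes used by the tests and the acceptance script

Storn runs use 2,500 evaluations with last-600 averaging, ten seeds.
Handle/Folium convergence traces use ten runs of 1,600 evaluations with a
two-stage (0.35, 0.15) schedule — at a fixed 0.35 an L2 proposal
undercovers the Handle's outer arms, and lowering the target is precisely
the method's mechanism for non-convex coverage. The 20-D anisotropic
benchmark uses the full five-stage schedule and 6×10⁴ evaluations per run,
ten runs per exponent; the 5-D sup-norm box uses 2×10⁴. The unit-disk
stationarity checks use 5×10³ evaluations per run. Phase-monotonicity
checks on the disk use 7.5×10⁴-evaluation runs with 5,000-evaluation
stationarity windows, averaged over three seeds, because per-phase means
carry correlated noise of order ±20–30% per run at low P.

## Numerical choices

* All volume arithmetic is in log-space (20-dimensional volumes overflow
  doubles); `normalized_volume` exponentiates log V / n.
* |det C − 1| ≤ 1e−9 is asserted after every step; renormalization divides
  the Cholesky factor by exp(mean log diag).
* A non-positive-definite covariance intermediate is repaired by flooring
  eigenvalues at 1e−12 of the largest, with a logged warning.
* Determinism: a run is a pure function of (oracle, start, config, seed);
  identical seeds give bit-identical traces.
* Degenerate inputs: infeasible starts raise before any sampling; a phase
  with no feasible sample is extended once, then the run aborts with a
  partial report; empty point sets and zero-extent boxes are handled
  explicitly.

## Known limitations

* The volume estimate carries a small positive bias (~3–5% at the default
  constants) from the coupling of radius control and hit smoothing; it
  shrinks with β and M at the cost of adaptation speed.
* Non-convex or disconnected regions can be undercovered — the estimate
  approaches vol(A) from below and different runs may center in different
  components; multi-start support returns all reports without merging.
* Very low hitting probabilities are expensive: equilibration needs
  O(1/(nβP)) evaluations per phase.
* The proposal family is affine Lp-balls only; regions far from any affine
  ball image (e.g. heavy-armed stars in high dimension) are approximated
  conservatively.
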