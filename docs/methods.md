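# Methods

## Problem and model

A double-J ureteral stent appears on an abdominal radiograph as a thin,
roughly vertical radiopaque curve with a coiled pigtail at each end. As the
obstructed ureter decompresses after insertion, the stent straightens; the
package quantifies that straightening from a pre-cropped, binarizable ROI
containing a single stent.

The geometric model is deliberately minimal: the stent body is a
single-valued curve `x(t)` of lateral position against axial row index `t`.
This holds for the near-vertical stents the ROI protocol selects
(single, clearly visible stents); it fails for a stent folded back on
itself, which the pipeline does not attempt to handle.

## Preprocessing chain

1. **Binarization.** Fixed threshold (`foreground >= threshold`) or Otsu's
   between-class-variance maximization (`auto`, the default; the threshold
   used clinically is not standardized, and Otsu is the conventional
   automatic choice for a bimodal stent-on-background ROI). A constant image
   under `auto` binarizes to all-foreground.
2. **Contour.** Largest 8-connected component only (specks from noise must
   not hijack the trace), then a clockwise Moore-neighbor boundary trace with
   Jacob's stopping criterion — the outer contour only, interior holes are
   ignored. A vectorized equivalent (fill holes, 4-connected erosion border)
   produces the identical point set on tubular masks and is what the large
   simulations use; the equivalence is asserted in the tests.
3. **Centerline.** Per axial row, the median of the distinct contour column
   coordinates on that row. The median rather than the midpoint of the
   extremes is a deliberate choice: when residual pigtail curvature leaves
   more than two contour points on one row inside the kept span, the median
   stays on the main body. For the dominant two-point case they coincide.
4. **End trim.** `floor(0.05 · n)` points removed per end (flooring never
   over-trims; the protocol fixes the fraction, the rounding rule is ours),
   discarding the high-curvature pigtail remnants.

## Curvature metrics

**Segment vector angles.** The trimmed centerline is partitioned into
`k = 100` contiguous segments (sizes differing by at most one, remainder on
the leading segments — the partition is over centerline points). Each
segment's direction is the principal axis of its centered point cloud (SVD;
identical to the dominant eigenvector of the 2×2 scatter matrix, which the
tests verify against a closed form). Directions are sign-normalized to a
non-negative axial component; otherwise the arbitrary sign of a line fit
makes near-identical segments read as ~180° apart. Angles come from
`acos(dot)`; an out-of-range dot product (floating-point overshoot) returns
exactly 0 — with sign-normalized vectors the only reachable overshoot is
just past +1, i.e. effectively identical directions. The radian→degree
factor is `180/π` by default; a `pi_approx` option (e.g. 3.14) reproduces
output of software that hard-codes the two-decimal constant — a 0.05% scale
factor with no effect on any test of significance.

Both pairings are implemented and reported: `consecutive` (adjacent segments
of one image; the per-image tortuosity) and `cross_timepoint` (same segment
index at the two visits; the per-patient direction change). Angles from
`acos` are non-negative, and the summary is their plain mean.

**Normalized mean slope.** Per consecutive point pair,
`gradient = Δlateral / Δaxial`; the axial coordinate is the independent
variable (the stent is near-vertical, so the reciprocal convention would
divide by ~0 on a straight stent). Absolute values are taken before
summing/averaging — signed slopes of a laterally symmetric curve cancel
regardless of curvature. Both the absolute sum and its mean over steps are
reported; the mean (normalized by step count) is the headline statistic
since it is comparable across centerlines of different length.

## Cohort statistics

All tests run on within-patient differences `post − pre`. Shapiro–Wilk is
reported but does not gate anything: both the paired t-test and the Wilcoxon
signed-rank test are always computed. Wilcoxon conventions: zeros dropped
(not Pratt), ties mid-ranked, statistic `min(W+, W−)`, exact null by dynamic
programming over doubled ranks for effective n ≤ 25, normal approximation
with continuity and tie corrections above. Effect size is paired Cohen's
`d = mean(diff)/sd(diff)` (n−1 denominator; magnitude quoted, sign kept in
the data model), and post hoc power uses the noncentral t distribution
(`df = n−1`, noncentrality `d√n`, two-tailed, α = 0.05 default), which is
the standard dependent-means power computation; at `d = 0` it returns α
exactly. A cohort whose differences have zero variance is returned flagged
`degenerate` rather than raising, so batch runs survive pathological input.

## Phantom generator

The phantom emulates what the measurement chain actually consumes: a binary
tube of half-width `tube_radius_px` around the midline
`x(t) = center + A sin(2πt/λ + φ)`, optionally with 270° circular pigtail
arcs rendered tangent to the body ends (reproducing the high-curvature end
artifact the 5% trim exists to remove), and i.i.d. salt-and-pepper pixel
flips. A single-frequency sinusoid was chosen because one amplitude
parameter is a clean monotone curvature dial with an analytic slope oracle:
the mean absolute midline gradient is computable by quadrature, and over
whole periods equals `4A/λ`. Rendering is midline supersampling (0.2-row
steps) followed by dilation with a Euclidean disk; the mask is verified to
be a single 8-connected component before noise.

Defaults (400×160 px, radius 3, A = 20, λ = 300, pigtail radius 8) are
scaled to a cropped stent ROI at typical radiograph resolution: a stent body
a few hundred rows tall, ~7 px wide, with lateral excursion an order of
magnitude larger than the tube width.

Cohorts draw per-patient pre amplitudes from Normal(μ, σ) truncated at 0
(truncation, not rejection, keeps the draw count and hence determinism
independent of the parameters) and set the follow-up amplitude to
`straightening_factor × A_i`, optionally plus independent per-patient jitter
(`post_amplitude_sd`, default 0) modelling variability in how far each
ureter straightens.

What the phantom does **not** model: radiographic physics (scatter, beam
hardening, bone background), anatomy-correlated curvature (a sinusoid is not
a ureter's shape), stent width variation, or inter-visit pose change beyond
axial misalignment. Passing phantom tests therefore demonstrates that the
measurement chain is correct and self-consistent, not that the metrics are
clinically valid on real radiographs.

## Simulation studies

**Power agreement.** The study condition is a cohort whose standardized
slope-difference is d = 0.5 with n = 30 patients. Design: at each visit the
amplitude is the visit mean plus independent Normal(0, τ) per-patient
jitter — insertion mean `A0 = 15`, follow-up mean `0.9·A0`. Because a
noise-free render is a deterministic response g(amplitude), the realized d
is `(E g(P) − E g(B)) / sqrt(Var g(P) + Var g(B))`; g is measured once
through the real pipeline on an amplitude grid fine enough (0.02 px) to
resolve its sub-pixel quantization wiggle, the moments are direct
normal-weighted sums over that grid, and τ is solved by root-finding so
that d = 0.5. The symmetric jitter
also makes the no-straightening null (visit means equal) exchangeable
between visits, so its type-I error is exact by construction, whatever the
shape of g. 1000 cohorts per arm are rendered and tested; the empirical
rejection rate is compared with the analytic noncentral-t power and the
null rate with the nominal 5%. Phantoms here are 260×72 px, tube radius 2,
λ = 200, no pigtails or noise — small enough that the ~120k rendered images
run in a few minutes on one core.

**Discrimination under misalignment.** 150 patients, pre amplitudes
~ truncNormal(18, 4), straightening factor 0.7, and a uniform integer axial
shift in ±5 rows between visits, implemented as the equivalent midline phase
shift (the ROI is re-placed relative to vertebrae at each visit, so a few
rows of misalignment is the realistic failure mode). Per patient both
metrics are computed at both visits and the paired |Cohen's d| values are
compared. The slope metric's effect dwarfs the consecutive-angle metric's:
with ~3-point segments the consecutive angles are dominated by quantization
jitter, and averaging local angles washes out gradual global straightening.

## Numerical choices and edge cases

- Coordinates: row = axial, column = lateral, origin top-left, 0-based.
- `Centerline.axial` admits any strictly increasing reals; raster-derived
  centerlines carry integer rows, analytic constructions (rotation
  invariance checks, quadrature oracles) use floats.
- Segments need ≥ 2 points; `split_segments` raises below `2k` points
  rather than silently merging.
- A segment of identical points raises `degenerate segment`; duplicate
  axial values in the slope metric raise (unreachable through the public
  chain, guarded anyway).
- Exact Wilcoxon enumeration doubles the mid-ranks so all rank sums are
  integers; the DP is over at most `n(n+1)` states.
- CSV output uses 6 significant digits for stable byte-level diffs; all
  randomness flows from a single integer seed per run.

## Known limitations

- The centerline model cannot represent a stent that is locally horizontal
  or folded; the contour median then mixes branches.
- The pigtail arcs are geometric stand-ins, not renderings of real coil
  projections; they exercise the trim logic, nothing more.
- The normal-approximation Wilcoxon branch (n > 25) is accurate to the
  usual continuity-corrected approximation, not exact.
- With `pi_approx = 3.14`, angles can nominally reach 180.09°; the bound of
  180° holds under the default π.
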