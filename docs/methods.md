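# Methods

This note documents the models, conventions and numerical choices
behind `refix`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Pair-delta geometry and return classification

All coordinates are screen-centered degrees of visual angle, x
rightward, y upward; readers of pixel data convert through the exact
arctangent formula (no small-angle approximation) in
`refix.io.GeometryConfig`.

For the saccade ending at fixation *i* and look-back depth *n*, the
reference vector is the **composite displacement** from fixation
*i−1−n* to fixation *i−1*.  For n=1 this is simply the previous
saccade; for n≥2 the composite choice is what makes "Δφ = 180°, Δa = 0"
coincide exactly with landing on the n-back fixation, which is the
property the classification thresholds are built around.  The turning
angle is unsigned and folded into [0°, 180°] — every statistic the
package computes uses only |Δφ|, so the sign is not retained.

Classification uses strict inequalities: return means Δφ > 178° **and**
|Δa| < 2°; forward mirrors this at Δφ < 2°.  Boundary values do not
qualify.  Both thresholds are arguments, not constants.  The circular
*return region* used by the temporal, saliency and foraging analyses
defaults to a 2° radius (strict inequality), also configurable.

Zero-amplitude saccades (consecutive identical coordinates) have no
direction; they are dropped with a logged warning rather than assigned
an arbitrary angle.

## Null models

**Shuffled baseline.**  Within each subject, the pooled saccade list
(amplitude, direction pairs) is permuted and re-chained from the origin
into pseudo-trajectories with the original saccade counts.  The
amplitude and direction multisets are exactly preserved (a permutation),
so any excess of empirical returns over this baseline is attributable to
sequential structure, not to the marginal distribution of saccades.
Shuffling is within subject because all downstream inference is
per-subject; pooling across subjects would mix different oculomotor
styles.

**Conditional Markov simulator.**  Per subject, the distribution
P(Δa, Δφ | a_prev) is estimated by histogramming saccade pairs: the
conditioning amplitude in 1° bins, Δa in 1° bins, Δφ in 3° bins.
(These are estimation bin widths; display binning elsewhere is 30°×2°
or 1°×1°.)  Simulation starts from a draw of the subject's empirical
first-saccade (amplitude, direction) sample and iterates: sample
(Δa, Δφ) given the current amplitude — falling back to the nearest
populated conditioning bin when the current one is empty, with a log
message — form the next amplitude a+Δa (non-positive draws rejected and
redrawn, capped, then the trajectory is aborted with a diagnostic), and
rotate the direction by ±Δφ with a uniformly random sign, since only
unsigned angles are stored.  Within a histogram cell the draw is
uniform.  No screen-boundary restriction is applied, so simulated
trajectories may leave the nominal display; the simulator models
saccade statistics, not the display.

A consequence of the binning worth knowing: the strict forward/return
criteria (2°) are narrower than the 3° estimation bin, so within-bin
uniform resampling smears a sharp empirical forward peak across the
bin and the simulator underproduces *strict-criterion* forward
saccades by up to roughly a third.  The acceptance suite therefore
checks forward-rate agreement on the scale of the fraction itself;
return rates, which spread more smoothly near 180°, reproduce within
the subject-level bootstrap CI.

**Comparisons.**  Empirical-vs-baseline differences use a percentile
bootstrap (default 2,000 resamples) over subjects of the mean paired
difference; "significant" means the 95% interval excludes zero.  KL
divergences use the natural logarithm with an ε = 10⁻⁹ regularizer
added to both histograms before renormalization.

## Fixation-duration models

The momentum model is continuous at both breakpoints:

    d(Δφ, Δa) = β₀ + s₁·min(Δφ, c) + s₂·max(Δφ − c, 0)
                   + u·min(Δa, 0) + o·max(Δa, 0)

Angle and amplitude terms are additive (no interaction).  The sign
convention for the amplitude slopes is explicit in the design matrix:
*u* multiplies min(Δa, 0) — the undershoot side, Δa < 0 — and *o*
multiplies max(Δa, 0), the overshoot side.  A positive *u* therefore
means undershooting (more negative Δa) *shortens* the fixation, and a
negative *o* means overshooting shortens it.

For fixed *c* the model is linear, so *c* is profiled: closed-form
least squares on a 1° grid from 10° to 170°, ties broken toward the
smaller *c*, then bounded scalar refinement within ±1° of the best grid
point.  When the profiled breakpoint does not improve on a single-slope
fit (relative SSE gain below 10⁻⁹ of the total variance) the
`c_identifiable` flag is false — constant-duration and no-break data
land here.  R² is computed as 1 − SSE/SST and defined as 0 when SST = 0.
Per-subject fits are the unit of inference; pooled fits exist for
display parity.

The inhibitory-hill alternative, d_B = intercept + k·exp(−‖C−A‖²/2σ²),
reads the hill's effect as the Gaussian kernel value at the outgoing
landing point (the natural "proportional to the distance between A and
C" reading; a separate linear distance factor multiplying the kernel
would add a parameter the data cannot separate from k at these scales).
σ is profiled over 0.25°–8° in 0.25° steps with intercept and k solved
linearly; the reported variance explained is on whatever response is
supplied, so fitting the hill on momentum residuals directly measures
what the hill adds beyond momentum.

**Residual null bands.**  Whether residual structure in a binned
(Δφ, Δa) map is real is judged against a sampling-density-dependent
band: for a cell with n observations, the null distribution of its mean
is that of n draws (with replacement) from the pooled residuals; the
2.5/97.5 percentiles over seeded bootstrap replicates widen exactly
where sampling is sparse.

**Return-trial alignment.**  Trials containing an n-back region return
are aligned on the second visit; control trials of the same subject are
aligned at a position drawn from the subject's empirical distribution
of return positions given trajectory length (nearest available length
when unmatched; subjects without return trials are skipped with a
warning).  Curves are means over subjects of per-trial means, with
subject-level bootstrap CIs; the `use_corrected` mode substitutes
per-subject momentum residuals, so a spatially specific slowing
survives while saccadic momentum is removed.  The out-location test
(per dataset, Bonferroni-corrected paired t) defaults to offset −1,
the fixation from which the return saccade departs — where the
classical IOR delay is measured.

## Saliency

Channels are luminance = mean(R,G,B), red/green = R−G, blue/yellow =
B−(R+G)/2, saturation = max−min, on [0,1]-scaled RGB.  The pyramid
downsamples by 2 per scale (3 scales); filter sigmas shrink with the
scale so each map measures a constant physical neighborhood, and
coarse maps are bilinearly upsampled back for lookup.  Default sigmas
are 1° (smoothing) and 0.5° (contrast kernel) when a pixels-per-degree
is supplied, otherwise 10 and 5 px; convolutions use reflective
padding.  Local contrast is sqrt(max(0, G∗F² − (G∗F)²)) — a smoothed
local standard deviation — and texture contrast applies it twice.
Maps are z-scored per image; constant maps become all-zeros with a
degenerate flag, and z-scoring is idempotent.  Additional features
(phase congruency, intrinsic dimensionality, interactions) enter
through `register_feature_plugin`; everything downstream is
roster-agnostic.

AUC is the Mann–Whitney statistic normalized by the pair count (ties
0.5).  The repeat/bootstrap protocol (150 repeats of 1,000 sampled
locations per group, 2,000 bootstrap resamples of the repeat values)
subsamples without replacement when the pool allows, with replacement
otherwise.  Feature lookup takes the nearest pixel — no interpolation —
after the degree→pixel mapping.  The logistic combination is
unregularized by default; a small L2 (argument `l2`) is available for
separable folds and is logged when used.  Evaluation is
leave-one-subject-out: weights trained on all other subjects' positives
vs controls, two AUCs (return locations vs controls, normal fixations
vs controls) on the held-out subject, averaged over folds.

## Priority maps and the multinomial comparison

Maps are 2-D histograms of contributing fixations at 0.25°/cell
default (0.5° in the bundled pipeline configuration — Δ values depend
on the grid only through the map values, so resolution is a logged
configuration item), blurred with a Gaussian of FWHM 1°
(σ = FWHM/(2√(2 ln 2)) ≈ 0.4247°) and normalized to unit mass; the
blur is truncated-renormalized at the border so Σp = 1 holds exactly.
Contributors are other subjects' trials on the same image that contain
no 1- or 2-back region return; provenance is recorded on the map.

The likelihood of a trajectory is multinomial in its cell counts (order
deliberately ignored).  In the return-vs-exploration comparison the two
visits of the return location count as the *same* event: the revisit is
tallied in the first visit's cell.  This keeps the comparison faithful
to its design — fixating one location twice versus adding one new
location — independent of how the grid resolution relates to the 2°
return region.  Because the return and exploration trajectories share
every other fixation, all common multinomial terms cancel and the
log-likelihood difference reduces exactly to

    Δ = log p_r − log p_l + log c_l − log c_r ,

with p the map values and c the counts at the return and last-fixation
cells; in the canonical case (two visits alone in their cell, last
fixation alone in its cell) Δ = log p_r − log(2 p_l), which changes
sign exactly at p_r/p_l = 2.  Cells without map support yield ±∞ and
are excluded from summaries with a logged count.  The multinomial
coefficient can be dropped (`with_coefficient=False`), under which a
flat prior gives Δ = 0 instead of −log 2; both readings are computable
because published flat-prior comparisons are ambiguous between them.
When multiple returns occur in a trial the first event is used.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults define the
study conditions under which the acceptance properties are evaluated.

* **Scene structure:** a mixture of Gaussian blobs (a broad central-
  bias component plus peripheral hotspots) acts as the generative
  priority map.  Blob centers are displaced per image (sd 1.5°) from a
  seeded substream, so images differ while sharing global statistics;
  the rendered images place luminance bumps at exactly these centers,
  linking image features to fixation density.
* **Fixation selection:** with probability `exploitation_weight`
  (default 0.6) the next target is a priority-map draw; otherwise an
  oculomotor move with von Mises direction about the previous direction
  (κ = 0.8 forward bias) and gamma amplitude (mean 6°), kept on screen.
  A κ = 0 oculomotor move approximates a uniform draw.  Subjects get
  seeded multiplicative jitter (sd 20%) on κ, amplitude scale and
  exploitation weight — real observers differ, and this is what makes
  between-subject KL divergence exceed subject-vs-own-simulator KL.
* **Return injection:** each candidate fixation becomes a 1-back return
  with probability 0.02 or a 2-back return with probability 0.01,
  accepted in proportion to the blob density at the revisited location
  (`return_salience_bias`), and lands uniformly in a 1° disc around it.
  Salience-biased acceptance encodes the empirical phenomenon that
  returns exploit relevant locations; the realized (post-acceptance)
  events are all recorded in the ground-truth sidecar.  With the 1°
  jitter only a fraction of injected returns satisfies the strict
  178°/±2° criterion (the lateral offset must stay under a·sin 2°), so
  strict-criterion fractions understate the injection rate by a known,
  recorded margin; region-criterion counts at radius ≥ 1° recover it.
* **Durations:** interior fixations follow the momentum model with the
  reference parameters (β₀ = 200 ms, s₁ = 0.383, s₂ = 0.002, c = 117°,
  u = 0.39, o = −2.75; β₀ is the package's choice, as no intercept is
  published) plus 50 ms Gaussian noise; a +40 ms bonus applies at both
  visits of every realized 1-/2-back revisit (radius 2°), injected or
  chance — return locations demand extra processing time regardless of
  how the revisit arose.  Endpoint fixations, which have no momentum
  observation, receive β₀ plus noise.  Durations are floored at 1 ms.
* **Trajectory lengths:** 3 + NegativeBinomial(r = 5, p = 5/17)
  fixations, mean 15 — typical of 5–6 s free viewing.

What the generator does **not** emulate: raw gaze samples, blinks,
calibration drift, measurement noise on positions, task effects,
image-content-specific semantics, or any dependence of saccade metrics
on image category.  Passing tests therefore demonstrate that the
analysis machinery recovers known structure of exactly these kinds;
they do not certify behavior on artifact-laden real recordings.

## Problem sizes and determinism

Every stochastic routine takes a seed; cohorts regenerate exactly from
(spec, seed), and the pipeline stamps its summary with the seed and a
configuration hash.  The test and acceptance suites use cohorts of 6–10
subjects × 6–8 images × 3–10 trials (about 5,000–12,000 fixations) and
50,000-observation recovery simulations — sizes at which every
qualitative property is stable across seeds while the whole suite runs
in about a minute.  Parameter-recovery tolerances come from the
reference fit's confidence envelopes (c ∈ [109, 124], s₁ ∈
[0.350, 0.416], s₂ ∈ [−0.13, 0.116], u ∈ [0.18, 0.60],
o ∈ [−3.02, −2.50]); at n = 50,000 and 50 ms noise each parameter falls
inside its envelope in ≈95% of replicates, and the acceptance test
allows the corresponding binomial slack.

## Known limitations

* The composite-vector definition of n-back deltas for n ≥ 2 is one of
  several defensible readings of a schematic; it is the one under which
  exact n-back returns sit at (180°, 0).
* Conditional-distribution estimation needs on the order of hundreds of
  saccade pairs per subject; below that, empty-bin fallback makes the
  simulator conservative.
* The hill model's σ grid tops out at 8°; data favoring broader hills
  saturate at the boundary (visible in fits as σ = 8.0).
* Empirical priority maps from few contributors have unsupported
  regions; trajectories touching them are excluded from foraging
  summaries (counted and logged) rather than smoothed over.
* The RS-trial exclusion for priority maps uses 1-/2-back region
  returns.  Excluding trials with *any* revisit would discard most
  realistic trials and systematically depress the map at its peaks —
  exactly where returns land — biasing the foraging comparison.
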