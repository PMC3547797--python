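# refix

Spatial, temporal and functional statistics of **return saccades** in
scanpaths — for eye-movement researchers studying inhibition of return
(IOR), saccadic momentum and fixation-selection strategies during scene
viewing.

When observers view images, their gaze sometimes returns to a location
fixated one or two saccades earlier.  Whether such return saccades are
*inhibited* (the classical IOR account, in which gaze is pushed toward
unexplored territory) or are part of a deliberate
exploration–exploitation trade-off is a quantitative question.  `refix`
implements the full analysis machinery needed to answer it on any
fixation-report dataset, together with a seeded synthetic-cohort
generator with known ground truth for validating every stage.

## What it computes

**Return-saccade geometry** (`refix.core`).  For the saccade ending at
fixation *i* and a look-back depth *n*, the reference vector runs from
fixation *i−1−n* to fixation *i−1*; the pair delta is the unsigned
turning angle Δφ ∈ [0°, 180°] between saccade and reference together
with the signed amplitude difference Δa.  A saccade is a **return** when
Δφ > 178° and |Δa| < 2° (exact landing on the n-back location gives
Δφ = 180°, Δa = 0), and a **forward** saccade when Δφ < 2° and |Δa| < 2°.

**Null models** (`refix.baselines`).  An order-shuffled baseline
(preserves each subject's amplitude/direction marginals exactly,
destroys sequence structure) and a conditional Markov simulator that
draws each saccade's (Δa, Δφ) from the per-subject estimate of
P(Δa, Δφ | a_prev).  The simulator reproduces all pairwise dependencies
— including the 1-back return rate — but cannot produce genuine 2-back
structure, which makes the empirical excess of 2-back returns over this
baseline the key spatial signature of facilitation of return.
Comparisons use subject-level percentile bootstraps; simulator quality
is validated by KL divergence.

**Fixation-duration models** (`refix.durations`).  The saccadic-
momentum breakpoint regression predicts the duration of fixation B in a
triplet A→B→C:

    d(Δφ, Δa) = β₀ + s₁·min(Δφ, c) + s₂·max(Δφ − c, 0)
                   + u·min(Δa, 0) + o·max(Δa, 0)

with a free critical angle *c* profiled by least squares, against a
Gaussian "inhibitory hill" alternative
d_B = β₀ + k·exp(−‖C−A‖²/2σ²).  Binned duration maps, residual null
bands, and the alignment of return-saccade trials on the revisited
fixation (raw and momentum-corrected) complete the temporal analysis.

**Saliency** (`refix.saliency`).  A 36-map feature bank (4 color
channels × 3 pyramid scales × {smoothing, local contrast, texture
contrast}), Mann–Whitney AUCs of fixated vs control locations (controls
drawn from fixations on *other* images), logistic RS/FIX saliency
models with leave-one-subject-out cross-validation, and the regression
of return-location AUCs on fixation AUCs across features.

**Priority-map foraging** (`refix.foraging`).  Empirical priority maps
(other observers' non-return fixations, 1° FWHM Gaussian density,
leave-one-subject-out), the multinomial log-likelihood of a
trajectory's cell counts, and the return-vs-exploration comparison: a
trajectory that keeps its revisit beats the equal-length variant that
explores a new location exactly when the priority at the return
location is more than **twice** that at the last fixation.

**Synthetic cohorts** (`refix.synthetic`).  Seeded generation of
subjects × images × trials with blob-shaped priority maps (per-image
layouts), a forward-biased oculomotor baseline, injected 1-/2-back
returns biased toward salient locations, momentum-model durations with
a duration bonus at return locations, matching rendered PNG-able
images, and a ground-truth sidecar.

## Worked example

```sh
refix all --config config.yaml --out results --seed 11
```

with `config.yaml`:

```yaml
cohort: {n_subjects: 8, n_images: 8, trials_per_image: 6}
n_boot: 1000
foraging: {resolution: 0.5, fwhm: 1.0}
```

generates a cohort of 5,971 fixations, runs every stage and writes
`results/summary.json`.  Key numbers from that run and how to read
them:

```
return_fractions   1-back 0.0100, 2-back 0.0087
baselines          1back_vs_shuffled   +0.0069  significant
                   1back_vs_simulated  +0.0014  not significant
                   2back_vs_simulated  +0.0044  significant
durations          piecewise: c=107.8, s1=0.391, s2=0.020,
                              u=0.374, o=-2.993, R²=0.088
                   hill:      k=29.4, sigma=8.0, R²=0.023
foraging           mean Δ log-likelihood  empirical -0.067 / flat -0.686
```

Reading: 1-back returns occur far more often than the shuffled
marginals predict, but the pairwise Markov simulator reproduces them —
while 2-back returns exceed even that baseline, the signature of
genuine facilitation of return.  The momentum model recovers its
generative parameters (the cohort was generated with c=117°, s₁=0.383,
s₂=0.002, u=0.39, o=−2.75) and explains ~4× more duration variance
than the inhibitory hill.  Keeping a return saccade costs −log 2 ≈
−0.69 under a flat prior but only −0.067 under the empirical priority
map: revisits target locations other observers also prioritize.

The same analyses run on real data from a fixation table
(`subject,image,trial,fix_index,x,y,duration`, degrees of visual angle,
or pixel columns plus a display geometry):

```python
from refix.io import read_fixation_table
from refix.core import count_returns

trajectories = read_fixation_table("fixations.csv")
per_subject, pooled = count_returns(trajectories, nback=2)
```

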