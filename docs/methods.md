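# Methods

This package implements a subsequent-memory analysis for a retro-cued
working-memory paradigm: multivoxel decoding of face/scene evidence
from ROI fMRI timeseries, followed by Bayesian estimation of the
"plasticity curve" relating scene−face classifier evidence during
working-memory trials to later recognition of the held scene, under the
non-monotonic plasticity hypothesis (NMPH).

## Experimental structure (design module)

All timing is integer seconds on a TR-aligned grid (TR = 2 s).  Phase 1
trials are 16 s (target 1 s, delay 7 s, probe 2 s, blank 6 s); Phase 2
stay trials are 20 s (target 4 s, delay 8 s, probe 2 s, blank 6 s) and
switch trials 28 s (an extra 8-s post-cue delay).  Blocks are preceded
by 20 s of dummy scans, giving 340-s Phase 1 blocks (4 x 20 trials) and
428-s Phase 2 blocks (6 x 18 trials, 12 stay : 6 switch); the scanned
session is 3,928 s.  Analysis windows are half-open `[a, b)` so the
pre-switch window (4–12 s) holds exactly 4 scans, post-switch (16–20 s)
2 scans and probe (20–24 s) 2 scans.  Classifier training scans come
from the final 6 s of each Phase 1 delay plus intertrial rest,
subsampled per block with a seeded RNG to 120 scans per class.

## Decoding (mvpa module)

Three one-vs-other L2-penalized logistic detectors (face, scene, rest)
are trained on individual 2-s scans after (a) shifting trial labels
forward 6 s for haemodynamic lag and (b) one-way ANOVA feature
selection at p < 0.05 across the three classes.  The penalty is
`lambda = 50` on the summed squared weights (`C = 1/lambda` in
scikit-learn's parameterization; the intercept is unpenalized);
cross-validation accuracy is flat over a wide lambda range, so nothing
hinges on the exact value.  Evidence is each detector's raw logistic
output in [0, 1] — deliberately not softmax-normalized, because the
detectors are trained independently and their outputs need not sum to
one.  Cross-validation is block-wise with feature selection re-run
inside each training fold (a deliberate strictness so the accuracy
estimate cannot leak); the final model for Phase 2 decoding selects
and trains on all Phase 1 data.  Accuracy is argmax over the three
detectors, ties broken in fixed (face, scene, rest) order.  No
scan-wise normalization is applied by default.

## Curve induction (pcit module)

The plasticity curve is a 3-segment piecewise-linear function f on the
rescaled evidence domain [−1, 1].  The prior draws the two interior
knot abscissae as order statistics of two Uniform(−1, 1) variates and
the four knot heights i.i.d. Uniform(−1, 1).  Each Phase 2 scene item
contributes learning events (its pre-switch and post-switch window
means in the combined analysis; a single event in interval-specific
analyses); evidence is rescaled once per analysis so the pooled minimum
maps to −1 and maximum to +1.

For a candidate curve, event effects are summed, Δ_i = Σ_m f(e_im), and
passed through a logistic link with a nuisance intercept:
p_i = σ(β0 + Δ_i).  The graded recognition outcome y_i ∈ {0, 1/3, 2/3,
1} enters a fractional-Bernoulli log-likelihood y log p + (1−y) log(1−p)
(exact thirds internally; this reduces to the Bernoulli likelihood for
binary outcomes).  β0 is profiled out per curve by a safeguarded Newton
iteration on the concave 1-D likelihood (bounded to ±20 on the logit
scale, step tolerance 1e-12); predicted probabilities are clamped to
[1e-12, 1 − 1e-12].  There is no free slope on Δ: a slope would trade
off against curve amplitude, which is already bounded by the knot
heights.  The curve's importance weight is its maximized log-likelihood,
normalized by log-sum-exp across the sample.

The posterior summary is the weighted pointwise mean curve on a 101-
point grid with a weighted 5th–95th percentile band (90% credible
interval).  A curve is theory-consistent (U-shaped, supporting the
NMPH) when its knot minimum falls strictly below its starting height
and some knot after the first minimizing knot strictly exceeds that
minimum.  The log Bayes factor is the log posterior-odds of consistent
versus inconsistent curves minus the log prior-odds, the prior odds
estimated from the same sample's unweighted labels; it is capped at
±10 (with a flag) only when a label class is absent from the sample.
An overall fit score is the likelihood-ratio statistic
2(LL[posterior-mean curve, profiled intercept] − LL[intercept only]),
floored at zero and referred to χ² with 1 degree of freedom by default
(the net curve effect treated as a single induced predictor; the df is
configurable and this interpretation is an open choice).  Partialing
analyses residualize one interval's evidence on the other by OLS with
intercept over the pooled items, then rescale the residuals.

Default sample size is 100,000 curves (configurable); the test and
acceptance profiles use 5,000, which stabilizes the sign of the log
Bayes factor at 756 items while keeping a laptop-scale runtime.  Work
is chunked over curves (4,096 per chunk) to bound memory.

## Resampling inference (resampling module)

Per-participant switch-trial counts (36) are too small to estimate a
nonlinear curve within subject, so items are pooled across participants
into a supersubject.  The permutation test shuffles outcomes across the
pooled items (a config flag restricts shuffling to within participant),
re-runs the full curve induction per permutation with a fresh curve
sample, and reports the fraction of null log Bayes factors that matched
or exceeded the observed one (200 permutations by default).  The
bootstrap resamples participants with replacement (duplicated
participants contribute duplicated items), re-runs the analysis per
replicate, and reports the fraction with positive log Bayes factor (200
replicates).  Rescaling to [−1, 1] is recomputed inside each analysis,
so it tracks each bootstrap pool and is automatically unchanged under
permutation.  Every replicate derives its RNG from (seed, replicate
index) and is individually reproducible.

## Behaviour (behavior module)

Recognition responses map to strengths 0, 1/3, 2/3, 1 (exact rationals;
0.333/0.667 are display roundings).  Recognition sensitivity is the
Mann–Whitney AUC (ties count one half).  Working-memory probe accuracy
is regressed on a per-trial evidence scalar by maximum-likelihood
logistic regression with a seeded percentile bootstrap over trials for
the 95% CI (1,000 resamples; percentile rather than BCa, as nothing in
the analysis depends on refined interval endpoints).  Complete
separation is reported with a flag and a slope capped at ±25 rather
than a crash.

## Synthetic studies (synth module)

The generator emulates the statistical structure the analysis assumes,
with full ground truth retained.  Each participant has unit-norm face
and scene voxel templates over a shared informative subset (60 of 200
voxels by default).  A trial's neural state is a pair of (scene, face)
amplitudes on the two templates; haemodynamics are a pure onset shift
of the amplitude boxcar (6 s in Phase 1, matching the label shift; 4 s
in Phase 2, matching how the analysis windows sit relative to trial
events — with a 6-s shift the pre-switch state would bleed into the
16–20 s window and the decoded sign pattern could not hold).  An
optional double-gamma HRF convolution sits behind a config flag.
Gaussian voxel noise (sd 0.3) is calibrated so block-wise
cross-validated face/scene decoding is comfortably above 90%, the
separability regime the analysis assumes for ventral temporal category
evidence.

Phase 2 amplitude pairs are drawn per trial from pre-switch
(scene-dominant) and post-switch (face-dominant) mixtures,
parametrized by a bounded uniform scene−face contrast (pre: [−0.3,
1.2]; post: [−1.2, 0.3]) and a normal total activation (mean 1.4, sd
0.1).  The bounded contrast matters: the curve-induction stage rescales
evidence by its pooled extremes, so the evidence axis must be sampled
densely out to its edges for curve shape to be identifiable there.
Participant heterogeneity enters as small normal offsets (sd 0.08) on
each participant's contrast and total means, giving the participant
bootstrap real between-subject variance.

Behaviour comes from a known ground-truth curve f\*: the rescaled
pre/post latent contrasts are separate learning events,
p = σ(1.0 + f\*(e_pre) + f\*(e_post)); a noisy copy of p (response
noise sd 0.05) is binned at 0.25/0.5/0.75 into the four graded
responses — a simple monotone coding that produces all four response
types.  The intercept puts old-item hit rates near 75%, the recognition
regime of this paradigm.  Lure items get baseline probability
σ(1.0 − 2.2).  Probe
accuracy is Bernoulli in the latent probe-window face amplitude,
σ(−0.3 + 2.0·f).  The default f\* is U-shaped (knots y = 0, −0.85,
−0.25, 0.9): high scene dominance strengthens, close competition
weakens, full face dominance leaves the scene memory unchanged to
slightly strengthened; a monotone-increasing curve is provided as a
negative control.  The latent evidence is retained for recovery tests
and never consumed by the analysis stages.

What the generator does *not* emulate: scanner drift, motion and
physiological noise, HRF shape variability, spatial voxel correlation,
stay-trial behaviour, and attention lapses.  Passing tests therefore
show the statistical machinery is correct under the assumed signal
model, not that the pipeline is robust to real-fMRI artifacts.

## What recovery tests show — and a known asymmetry

With the default U-shaped f\*, the full pipeline (generate → decode →
pool → curve induction, 756 items, 5,000 curve samples) returns a
positive log Bayes factor with a wide margin (typically +2 to +4.5)
across seeded replicates, and permutation p-values are calibrated
(uniform under a null generator).

The converse direction is intrinsically weaker: under a
monotone-increasing f\* the log Bayes factor concentrates slightly
below zero (roughly −0.15 ± 0.35 across studies) rather than strongly
negative.  Two properties of the procedure combine to cause this.
First, rescaling by the pooled minimum/maximum anchors the domain at
extreme observations; under any realistic decode measurement noise the
anchors are noise-selected outliers, so the domain edges are
data-sparse.  Second, the consistency label requires only an
arbitrarily small dip below the starting knot, so near-monotone curves
that dip in a data-sparse region fit monotone data essentially as well
as monotone curves, keeping the posterior consistent fraction near the
prior fraction.  With noise-free evidence sampled densely to the domain
edges the expected strongly negative scores do appear, confirming the
machinery.  Practically: this implementation (like the procedure it
follows) can provide strong evidence *for* a U-shaped curve but only
weak evidence *against* one; negative log Bayes factors near zero
should be read as "no support", not "strong refutation".

## Numerical and reproducibility notes

- One master seed per run; per-participant and per-stage substreams are
  spawned via `numpy.random.SeedSequence`, and every resampling
  replicate derives its RNG from (seed, replicate index).
- Vectorized curve evaluation uses per-segment slope/intercept gathers;
  it matches `numpy.interp` to 1e-12 on random curves (zero-width
  segments take the left knot's height, a measure-zero convention).
- Degenerate inputs are first-class errors: constant evidence cannot be
  rescaled, empty classes cannot be trained, windows must lie inside
  trials on the TR grid, duplicate item ids are rejected.
- Effective sample size of the posterior is reported and a warning is
  raised below a floor of 50; at 756 items and 5,000 samples the ESS is
  typically 20–600 depending on likelihood sharpness, which is ample
  for the sign of the log Bayes factor (importance-sampling sd ≈ 0.1)
  but the credible band should be read qualitatively at that scale.
- Test and acceptance problem sizes (5,000 curve samples; 200
  permutation/bootstrap replicates; scaled-down designs in unit tests)
  are the package's desk-scale profile; all defaults remain at study
  scale.
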