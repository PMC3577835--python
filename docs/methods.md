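# Methods

## Problem and model

Female *Gryllus bimaculatus* crickets approach conspecific calling songs
(positive phonotaxis).  The song is an amplitude-modulated tone whose
envelope carries information on two time scales: short sound pulses grouped
into longer chirps.  The behavioral response to a song is summarized by a
phonotactic score in [-1, 1], averaged over the females tested with that
pattern.  `phonotaxnet` models the mapping from a song's temporal features
to this mean score with a small one-hidden-layer perceptron

    y = c + sum_j v_j * sigma(b_j + sum_i W_ji x_i),   sigma(a) = 1 / (1 + e^-a),

and uses that regression model to ask which features matter: it predicts
scores for untested patterns (response fields), quantifies how the two time
scales combine, and searches all 255 subsets of the eight candidate
features for the most informative ones.

The hidden nonlinearity is the logistic function; "sigmoidal" admits
several shapes and the logistic is the conventional default.  Hidden and
output units carry bias terms: the features are whitened to zero mean
before training, and without biases the network would be forced through the
origin of the whitened space, a needless restriction.

## Song features

Eight redundant descriptors, fixed canonical order (units: ms, duty cycles
dimensionless):

pulse_duration (Pdur), pulse_pause (Ppau), pulse_period (Pper),
pulse_duty_cycle (Pdc), chirp_duration (Cdur), chirp_pause (Cpau),
chirp_period (Cper), chirp_duty_cycle (Cdc).

On each scale `period = duration + pause` and `duty_cycle = duration /
period`, so two non-redundant descriptors per scale determine all four;
`complete_pattern` solves any admissible 2+2 parameterization and rejects
redundant or inconsistent pairs (e.g. a pause of 0 with duty cycle 1 leaves
the period free; a duration exceeding a given period implies a negative
pause).  Durations must be positive, pauses non-negative (a zero pulse
pause — a continuous tone within the chirp — is legal), duty cycles in
(0, 1].  No constraint ties the two scales together (a chirp need not
contain an integer number of pulses): the analyses vary them on independent
grids.

## Synthetic behavioral data

The original trackball data are not deposited, so a generator stands in for
them.  It is **synthetic**: it emulates the statistical structure the
analyses rely on, not the animal.

Ground truth.  Attractiveness factors on the two scales, each in [0, 1]:

* pulse factor: a Gaussian in pulse period (optimum 40 ms, sd 8 ms — at
  least 0.5 across 35-45 ms) times a band response in pulse duty cycle
  (flat on 0.4-0.7);
* chirp factor: a band response in chirp period (flat on 250-500 ms) times
  one in chirp duty cycle (flat on 0.3-0.7).

Band responses are smoothed top-hats with raised-cosine flanks (flank
widths 200 ms, 0.3, 0.3); only the optima and flat ranges of the real
tuning are documented, so the flank shape is a modelling choice — smooth,
bounded, monotone.  The factors fuse multiplicatively (`product`, AND-like:
both scales must be attractive) or, as a contrast condition, by a maximum
(`max`, OR-like), and the fused response is mapped onto [floor 0.0, peak
0.9].  With the product rule, chirp periods just above 500 ms still elicit
intermediate scores at an optimal pulse period (the flank), while far-off
periods elicit none.

Female panels.  Each pattern is "tested" by n females with n drawn from a
rounded log-normal clipped to [8, 225] and calibrated to mean 31 (sigma
0.8 gives the documented skew).  Each female's score is ground truth plus
Gaussian noise (sd 0.2 score units, of the order of the across-female
variability in the original data) clipped to [-1, 1]; the dataset stores
the panel mean, sd, and n.

Design.  The default design places 218 patterns on the planes the analyses
probe: a 7x7 pulse duration x pause grid at a fixed attractive chirp
(200/333 ms), a 7x7 chirp duration x pause grid at a fixed attractive pulse
(20/20 ms), an 8x7 period x period grid at duty cycles 0.5, and 64 probe
patterns on the response flanks (detuned periods, detuned duty cycles, far
off-optimum scales).  Grid values were calibrated once, against the
ground-truth surface, so that the mean-score class composition approximates
the documented 35% unattractive / 48% intermediate / 17% attractive split;
the heavy flank sampling this requires is itself realistic — about half of
the original patterns were intermediate, which only happens when the
transitions are probed densely.  The design is frozen; `random_design`
provides an alternative in which all eight features vary independently
(used by the recovery experiments).

What the generator does *not* emulate: individual-female response profiles
(noise is i.i.d. across females), any dependence of panel size on
attractiveness, drift between experimental sessions, and measurement error
in the features themselves.  Passing recovery tests therefore show that the
pipeline recovers the structure this generator encodes at realistic noise
levels — not that the original biological conclusions are reproduced.

## Preprocessing

Scores < 0.2 are unattractive, > 0.6 attractive, the closed interval
[0.2, 0.6] intermediate (boundary scores go to the middle class — the most
literal reading of "between").  All divisions of the data are stratified by
these classes: the 218 patterns split 200/18 into train/test with
largest-remainder proportional quotas, and cross-validation uses stratified
k-fold (backed by scikit-learn's `StratifiedKFold`, shuffled and seeded).

Whitening projects the features onto the principal components of the
training rows and scales each to unit variance (eigendecomposition of the
sample covariance; all components retained).  A numerically singular
covariance — any subset containing {duration, pause, period} of one scale
is exactly collinear — raises an error carrying the null directions rather
than silently truncating, because truncation would change the model's input
dimensionality.  The transform is always applied, never refit, on held-out
rows; inside cross-validation it is refit on each fold's training part (a
flag restores the variant that reuses one global training-set transform).

## Training

Full-batch RProp minimizes the training MSE for a fixed budget of cycles
(default 10,000; no early stopping, so architectures are compared at equal
budgets).  Per-parameter step sizes start at 0.1 and grow by 1.2 on
consecutive same-sign gradients (cap 50) or shrink by 0.5 on a sign flip
(floor 1e-6), with the flipped parameter's update suppressed for that cycle
(no weight backtracking).  These are the canonical published constants.
Initial weights are i.i.d. uniform on [-0.5, 0.5].  Non-finite parameters
raise a divergence error; they are never returned silently.

## Model selection

A model spec is (feature subset, hidden-layer size).  Quality is the
validation MSE of stratified 5-fold cross-validation, repeated (default
100x) with fresh initial weights, folds redrawn each repeat (a fixed-folds
mode reproduces the reading in which only the weights are re-randomized),
and averaged.  The hidden-layer size is the smallest n whose successor
improves the validation error by no more than 1%, measured relative to the
1-unit error E(1) — i(n) = 100 (E(n) - E(n+1)) / E(1); a flag switches the
denominator to E(n).  If no n qualifies within the scan the maximum is
returned with a warning.  The exhaustive search applies this to all 255
subsets and ranks the selected models by validation MSE; exactly collinear
subsets fail whitening, are flagged, and rank last.  Ties break toward
smaller subsets, then fewer hidden units, then canonical order (parsimony,
determinism).  Pairs of models are compared with a two-sided Wilcoxon
rank-sum test on the per-repeat validation errors at alpha = 0.01
(scipy's normal-approximation `ranksums`; an exact-enumeration oracle
validates it at small n in the tests).

## Prediction and response analysis

For predictions the selected network is retrained from scratch (default
100x) on the whitened full dataset and predictions are averaged; the
across-member sd isolates initialization variability.  The whitening
transform is deterministic given the data and is computed once per
ensemble.  A response field evaluates the ensemble over a 2-D grid of two
features with the remaining degrees of freedom fixed (grid points whose
completion is invalid are excluded and carry NaN).  Default grids: pulse
axes 10-80 ms at 2.5 ms, chirp axes 50-900 ms at 10 ms.

Fusion index.  The period x period field at duty cycles 0.5 is summarized
by

    value = clip((r_both - max(r_pulse_only, r_chirp_only)) / (r_both - baseline), 0, 1)

with r_both the field maximum over attractive pulse periods (35-45 ms) x
attractive chirp periods (250-500 ms), r_pulse_only / r_chirp_only the
maxima over the two mixed regions, and the baseline the field minimum.
Near 1 the field requires both scales (AND); near 0 either suffices (OR).
The index is a scalar invention summarizing a qualitative pattern.  The
mixed regions must lie beyond the response flanks: the unattractive strips
default to pulse period > 60 ms and chirp period > 700 ms, because at
500-700 ms the chirp factor is merely detuned, not unattractive, and a
mixed-region maximum taken there would be blind to the fusion rule (both
rules give near-peak responses on the flank).  All boundaries are
configurable.

Calibration.  The sigmoid g(y) = -1 + 2 / (1 + exp(-a (y - b))) maps raw
predictions onto (-1, 1); (a, b) minimize the training MSE (coarse
log-slope x midpoint grid seeding Nelder-Mead).  Calibration is fit once on
the averaged training predictions.  When even the best sigmoid cannot beat
the raw predictions — the case when the observed scores are not a saturated
readout of the latent attractiveness, as with the plain default generator —
the sigmoid closest to the identity on the prediction range is returned,
flagged, with a warning, so applying the calibration is always safe.

## Numerical choices and degenerate inputs

* Feature-consistency checks use relative tolerance 1e-9; whitening rank
  tolerance is 1e-10 of the largest eigenvalue.
* The logistic is evaluated in a numerically safe split form; calibration
  uses `scipy.special.expit`.
* Pearson correlation on constant inputs, rank-sum tests with fewer than
  two repeats, and calibration on constant predictions are errors, not NaN.
* Ensembles drop diverged members with a warning and fail above 10%
  divergence.

## Reproducibility and problem sizes

Every stochastic operation takes a `numpy` Generator (or seed); the
pipeline driver spawns per-stage child seeds from one master seed via
`SeedSequence`, and equal seeds give bit-identical outputs.  The analysis
scripts and tests run at desk-scale budgets chosen to keep the full suite
in the minutes range while leaving the conclusions stable across seeds:
ensembles of 10-20 members at 2,000 RProp cycles (instead of 100 x 10,000),
and the 255-subset search at 1 repeat x 300 cycles with the hidden-unit
scan capped at 2 (instead of 100 repeats x 10,000 cycles).  The full-study
settings remain the defaults of the library functions.

## Known limitations

* The score surface, noise model and design are inventions constrained by
  documented summary statistics; none of the quantitative results on
  synthetic data (MSEs, correlations, p-values) are estimates of the
  original study's values.
* The 1% rule is sensitive to CV noise at reduced repeat counts; at desk
  budgets the selected hidden-layer size varies by a few units between
  seeds.
* The fusion index collapses a 2-D pattern into one number and depends on
  its region boundaries; it is meant to separate AND-like from OR-like
  surfaces, not to measure fusion strength on an absolute scale.
* Exactly collinear feature subsets are treated as errors by design; a
  pseudoinverse variant would rank them but change the feature-space
  dimensionality mid-search.
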