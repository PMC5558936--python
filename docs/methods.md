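# Methods

This note records the modelling conventions, defaults and numerical choices
behind `imitkin`, and what the synthetic benchmarks do and do not show.

## Kinematic extraction

**Filtering.** Trajectories sampled at 120 Hz are low-pass filtered with a
zero-phase (forward–backward) Butterworth filter, default 2nd order with a
10 Hz cutoff — standard practice for hand kinematics, where voluntary
movement content sits well below 10 Hz and tracker noise above it.  The
forward–backward pass squares the magnitude response (passband gain
`1/(1+(f/fc)^4)` for order 2) and removes phase lag, so event times such as
the velocity peak are not shifted.  Cutoff and order are arguments
everywhere they matter.

**Segmentation.** Movement onset is the first sample of the earliest run of
6 consecutive samples (48 ms) with speed above 10% of the trial's peak
speed; the offset is the last sample before speed stays below that
threshold for 6 consecutive samples.  Two conventions are fixed here:
thresholding uses |velocity| of the horizontal (movement) axis, not the 3-D
tangential speed; and the offset search starts after the speed peak — a
literal "first below-threshold run after onset" can end the window before
the peak on noisy data, which would violate the invariant
onset < argmax(speed) ≤ offset.  Trials with no qualifying run are
segmentation failures and are excluded like flagged error trials.

**The 20 parameters.** Computed on the onset–offset window: duration; peak
velocity (magnitude of the extreme horizontal velocity); peak acceleration
(maximum) and peak deceleration (most negative acceleration, reported
signed); times of these events from onset, also expressed as percent of
movement time and percent of horizontal path; horizontal max amplitude
(max − min x in the window); vertical amplitude (max y minus y at onset)
and its timing/location; and the dimensionless jerk

    DJ = -(D^3 / v_peak^2) * ∫ j(t)^2 dt        (trapezoidal integration)

with D the window duration and j the third derivative of horizontal
position.  The minimum-jerk movement attains −204.8 under this
normalisation on its full profile (720/1.875²); on the 10%-threshold
window the same profile evaluates to ≈ −56.7, which the tests verify
against numeric integration.  The sign convention makes *less* smooth
movements *more* negative.  An alternative `D^5/A^2` normalisation exists
in the literature; the `D^3/v_peak^2` form is used because peak velocity is
itself one of the extracted parameters and the tests have a closed form for
it.  Percent-of-path fields are clamped to [0, 100] to absorb numerical
overshoot at the window edges.

One row of the canonical parameter table deserves a note: the fourth
parameter is named "percent peak acceleration" in the source material but
described as the percent of horizontal movement at which peak *velocity*
occurs; the description wins, so parameter 4 is the percent-of-path
location of peak velocity (parameter 10 covers peak acceleration's
location).  Acceleration units are mm/s².

**Aggregation.** Per participant and condition, the mean and sample SD
(n−1 denominator, conventional at 8 trials) of each parameter over the
usable trials; a participant-condition cell needs at least 2 usable trials,
and participants with any missing cell are dropped with a report
(complete-case analysis).  Derivatives are central differences with
one-sided endpoints.

## Feature tables and indexing

A feature is one (condition, statistic, parameter) triple; the canonical
CSV uses self-describing headers `NTF_SD_P16` etc. plus `PARTICIPANT` and
`LABEL` (ASC/CTRL) columns.  In a two-condition SD matrix the global index
runs 1–40: 1–20 are the first condition's parameters in table order, 21–40
the second's, so index 37 is the vertical-amplitude SD of the second
(No-Target Elevated) block.  Analysis-ready matrices contain no missing
values by construction.

## Classifiers

Gaussian Naive Bayes is implemented in the package: class-conditional
per-feature Gaussians with maximum-likelihood variances floored at
`1e-9 × max per-feature variance` of the training data (with a 1e-12
absolute guard for degenerate constant data), prediction by maximum
log prior + log likelihood, exact ties to the control class.  The
closed-form densities admit fully vectorised leave-one-out evaluation via
rank-one downdates of the per-class sums, and leave-one-feature-out
evaluation by subtracting one feature's log-density contribution — this
makes the LOPO selector and the permutation nulls O(n·d) per table instead
of O(n²·d²), which is what keeps the nested benchmarks tractable.  One
consequence of per-feature Gaussians: NB posteriors are invariant to
per-feature affine standardization (the Jacobian term cancels between
classes), so the fast NB paths skip scaling; the tests assert equivalence
with the explicit standardize-and-refit route.

SVMs (linear and RBF), the information-gain decision tree and the
500-tree random forest are scikit-learn estimators behind thin wrappers;
the linear SVM exposes its hyperplane weights for feature ranking.
Hyper-parameters come from an exhaustive grid search over
`C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}` and `γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}` scored by
stratified inner cross-validation (default 5 folds), ties broken toward
smaller C then smaller γ.  Features are z-scored with training-fold
statistics before SVM and PCA (scale-sensitive); constant columns get unit
scale.  Whether the original analysis standardized is unknown; this is the
package's choice and the study-data tolerance (±1 held-out sample)
acknowledges it.

Metrics: with ASC the positive class, sensitivity = 100·TP/P,
specificity = 100·TN/N, accuracy = 100·(TP+TN)/(P+N).  Reports round
halves away from zero (13/16 → 81.3), since Python's default banker's
rounding would print 81.2.

## Condition screen and averages

The screen grid is leave-one-out NB accuracy for each condition under
feature groups I (20 means), II (20 SDs), III (both).  Row/column averages
are computed from the **unrounded** accuracies and reported at 1 dp with
half-up rounding; averaging the 2-dp printed cells instead can differ by
one rounding step at exact boundaries (e.g. a column averaging 48.75
reports as 48.8, while its printed cells average 48.74875 → 48.7).

## Feature selection

* **SVM weights**: |w| of the linear SVM fit at the grid-searched C on the
  standardized training matrix; top 8.
* **LOPO**: baseline LOOCV NB accuracy minus the accuracy with feature j
  removed; positive = discriminative; top 10.
* **PCA**: |first-PC loading| as a share of the summed absolute loadings,
  in percent; explained-variance ratios normalised to sum to 1; top 3
  within the combined rule, top 6 standalone.
* **Combined**: SVM top-8 ∪ (PCA top-3 ∩ LOPO top-10); 8–11 features.

All ties break by ascending global index, making every ranking
deterministic.  A structural consequence: on signal-free data most LOPO
scores tie at exactly zero (removing a feature flips no fold), so the
tie-break fills the LOPO top-10 with low indices.  The null-calibration
tests therefore assert uniformity of LOPO hits over features with nonzero
scores; the SVM, PCA and combined selections are tie-free in practice and
uniform as-is.  Inside an outer CV loop, per-iteration selections are
tallied into occurrence counts and the final reported set is the top-m
(default 9) by occurrence.

## Nested evaluation

Outer leave-one-out over participants; within each iteration,
standardization statistics, the selector and the grid search are computed
on the 29 training participants only (selection once per outer iteration,
hyper-parameters by stratified 5-fold inner CV on those 29 — the inner
split sizes were not specified in the source analysis, and once-per-
iteration selection is the default of the two defensible readings).  The
model is refit on all 29 with the chosen features/parameters and predicts
the held-out participant.  Per-fold seeds derive deterministically from the
run seed and outer index, so identical configurations reproduce
bit-identical results.  `selector="none"` reduces the machinery to plain
LOOCV and is asserted prediction-identical to the single-layer
implementation.

The design's central contract is absence of leakage: on label-permuted
data the nested accuracy must sit at chance.  The permutation-null test
bounds the mean of 100 permutations by chance plus the binomial standard
error of the pooled predictions.  Note that per-permutation accuracies are
*overdispersed* relative to a pure binomial: the 30 leave-one-out folds
share 28 of 29 training samples, so their errors are positively correlated
and individual permutation accuracies stray outside the n=30 binomial band
more than 5% of the time even for a correct implementation.  The band-
coverage assertion is set accordingly (≥75%); the optimism bound on the
mean is the assertion that actually detects leakage.

## Synthetic data generator

The generator emulates the study design: 8 conditions (Target/No-Target ×
Normal 48 bpm / Fast 58 bpm / Short 10 cm / Elevated curved; amplitude
15 cm except Short), 8 trials per condition per participant, one analysable
movement per trial.  A trial is ≥0.3 s rest, a minimum-jerk horizontal
profile of nominal duration 60/tempo s and extent = condition amplitude, a
raised-cosine vertical lift (8 mm for flat trajectories, 60 mm for the
elevated movement — the demonstrator's true vertical amplitude is not
documented, so this is a free parameter), rest, plus 1 mm i.i.d. position
noise.  Control-level trial-to-trial jitter is Gaussian on duration (5% of
nominal), extent (4%) and lift (20%).

Group structure enters as per-condition multipliers on that jitter: the
default ASC effect doubles variability in No-Target Fast and halves it in
No-Target Elevated, matching the reported *direction* of group differences
(higher ASC SDs for fast goal-less imitation, lower for the unusual
elevated movement); the magnitudes are generator choices, not measured
values, picked so a 30-participant cohort separates clearly.  Error trials
(default 6% ASC, 2% control, matching the study's exclusion rates) are
flagged as recording dropouts (a frozen-position chunk) or imitation
errors.

What this does and does not show: passing benchmarks demonstrate that the
pipeline recovers planted structure of a known form (independent Gaussian
features, variability-based group differences, one clean movement per
trial) and that it extracts nothing when no structure exists.  Real
recordings have correlated parameters, non-Gaussian and participant-
specific variability, multi-movement trials and tracker artefacts beyond
the two simulated error modes; synthetic accuracies (often 90–100% at the
default effect sizes) say nothing about achievable accuracy on real
cohorts.

## Benchmark problem sizes

The shipped benchmarks use 30-participant tables (14 ASC + 16 controls,
matching the analysed study sample), 100 seeds for recovery rates, 20
tables for nested-accuracy means, 100 label permutations for the null, and
150–500 seeds for the null-calibration tallies — enough for stable
Monte-Carlo estimates at the asserted thresholds while keeping the default
suite and the acceptance script inside routine desk runtimes.

## Known limitations

* The deposited study spreadsheet's internal layout could not be inspected;
  the `s1_spreadsheet` reader expects the canonical header convention in
  xlsx form and may need a mapping adjustment against the real file.
* No gap-filling of dropped tracker samples (such trials are excluded), no
  probability calibration, no multiclass support, no bootstrap confidence
  intervals.
* The c4.5-style tree uses entropy splitting without c4.5's pruning; it is
  a comparison baseline, not a headline method.
* With balanced-ish leave-one-out folds, NB fold priors are slightly
  asymmetric (14/15 vs 15/14 of 29); redundancy arguments that assume
  symmetric priors (e.g. "removing a duplicated column changes nothing")
  hold only up to borderline folds.
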