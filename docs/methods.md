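# Methods

This note documents the models, algorithms and numerical choices behind
`p300select`, and what its synthetic data can and cannot show.

## The analysis problem

A 4-choice P300 speller presents four pictures; their labels flash one at a
time (each label once per block, ten blocks per trial).  The flash-locked
EEG epoch following the attended label contains the N200/P300 event-related
response; the other three do not.  Calibration fits a discriminant to
target vs non-target epochs; a trial is classified by summing the per-flash
discriminant scores for each choice and taking the arg-max (ties to the
lowest choice index).

Standard home-use systems record a fixed 8-electrode subset (Fz, Cz, P3,
Pz, P4, PO7, PO8, Oz here — configurable, since vendors differ).  Users
whose response topography is spatially atypical — restricted, lateralized,
or noisier, as in severe cerebral palsy — may be poorly served by this
fixed subset.  The package implements the individualized alternative: a
wrapper search over the full 32-channel cap for an 8-electrode subset that
maximizes that user's calibration accuracy.

## SWLDA calibration

Features: each epoch is cropped to 0–800 ms post-stimulus, linearly
detrended per channel (least-squares line removed, which also removes the
mean), and decimated to ~20 Hz by non-overlapping block means with integer
factor `round(fs/20)` (30 at 600 Hz → 16 bins/channel; 13 at 256 Hz → 15
bins/channel, an effective 19.7 Hz accepted as the nearest integer-factor
approximation).  The original tool's decimation method (averaging vs pure
subsampling) is not documented; block means were chosen as the
anti-aliasing option, with subsampling available behind
`FeatureConfig(method="subsample")` for sensitivity checks.  Columns are
channel-major; no baseline correction or normalization beyond detrending.

SWLDA is the classical stepwise construction: ordinary least squares of
coded labels (+1 target, −1 non-target, intercept included via centering)
with forward entry of the candidate column whose partial-F p-value is
smallest and below `p_enter = 0.10`, backward removal of included columns
whose partial-F p-value exceeds `p_remove = 0.15`, a cap of 60 features,
and an iteration safeguard.  Degrees of freedom are `(1, n−k−2)` for entry
and `(1, n−k−1)` for removal with `k` currently included columns.  The
loop runs on centered cross-products via the reversible sweep operator, so
a selection wrapper can fit thousands of candidate models by slicing one
cached Gram matrix; a numba-compiled inner loop mirrors the numpy
reference implementation operation-for-operation (their agreement is
asserted in the tests).  Candidates whose adjusted sum of squares falls
below `1e-10` times their original sum of squares are skipped as rank
deficient.  If no feature passes entry, the session "could not calibrate"
and a `CalibrationError` is raised; selection wrappers score such subsets
as accuracy 0.

Calibration accuracy is resubstitution trial accuracy on the calibration
trials at the full flash count — deliberately the quantity a calibration
program reports, and distinct from held-out accuracy.  An important and
measured consequence: stepwise selection makes resubstitution accuracy
optimistically biased.  On pure-noise sessions (30 trials, 8–32 channels)
it sits around 0.55–0.75 rather than at the 0.25 chance level, because the
entry test greedily absorbs the most favorable noise columns.  Both arms
of every comparison (custom and default) carry this same bias, so paired
comparisons remain meaningful; chance-level claims do not, which is why
the chance-level study (below) scores held-out trials only.

## Electrode selection

Greedy forward search: starting from the empty set, every
`chosen ∪ {candidate}` subset is evaluated by refitting SWLDA and taking
resubstitution accuracy at 10 flashes; the arg-max candidate joins the
chosen set until M = 8 electrodes.  Accuracy ties are broken toward the
electrode earlier in montage order, making runs exactly reproducible.  An
exhaustive-search oracle over all C(|pool|, M) subsets (guarded by an
enumeration cap) backs the greedy search in the tests.

For held-out evaluation the subset is a hyper-parameter fitted by
leave-one-trial-out consensus: with N calibration trials, the greedy
search runs N times on N−1 trials; an electrode added at rank k in a fold
earns `max(0, M − k + 1)`; scores sum over folds and the top-M electrodes
form the consensus subset.  (The source formula's summation indices
starting at 0 are read as "over all folds and electrodes", with 1-based
ranks so the first-added electrode earns M; any other reading contradicts
"score based on the order".)  Ties at the M-th slot break by the better
(smaller) best rank across folds, then montage order.  The final model is
fit on all N trials restricted to the chosen subset.  Whether the original
per-fold searches used all 32 electrodes or only the default 16 is
unstated; the full cap is the default, configurable via the pool.

Comparisons between two calibrations use the flash-count tie-break: if
accuracies agree at r = 10 flashes, r decreases (9, 8, …, 1) and the first
differing r is reported; a tie at every r reports r = 1 with a tie flag.

The subset-size curve reports accuracy after each greedy addition and the
smallest size reaching 95% of the subset's own 8-electrode accuracy
(degenerate zero-accuracy trajectories need 1 by convention).

The generalization experiment holds out 20 randomly chosen trials
(seeded), runs consensus selection and both final fits on the remaining
trials, and applies both models to the holdout.

## Individual and group statistics

The individual improvement test models the n calibration trials as i.i.d.
Bernoulli with the default subset's success rate as the MLE,
`p̂ = k_default/n`, and reports the one-sided tail probability
`P(X ≥ k_custom) = Σ_{j=k_custom}^{n} C(n,j) p̂^j (1−p̂)^{n−j}` by direct
summation (exact integer binomial coefficients; degenerate `p̂ ∈ {0, 1}`
handled by the point-mass distribution).  P-values are reported raw, as in
individual-effects analyses; a Bonferroni column is available for user
judgment.  When only fractional accuracies are available, counts are
recovered as `round(acc × n)`.

Group-level mixed-effects modeling is out of scope (it requires the
original participant data); `summarize_groups` instead reports per-group
means and seeded percentile-bootstrap confidence intervals of the paired
improvement over subjects, clearly a descriptive summary, not the source
study's inferential model.

## Synthetic sessions

The generator produces the statistical structure the analysis needs, not
biophysical EEG.  Target epochs add a sum of Gaussian-in-time components,
each spatially weighted by a Gaussian-in-scalp-distance topography over
schematic 10-10 grid coordinates (signed lateral index, anterior-posterior
row; unitless).  The subject-level topography allows an anisotropic
(x, y) spread, and each component may offset its center — this is what
lets a profile place, e.g., its N200 posteriorly and P300 anteriorly, so
nearby electrodes carry partly non-redundant information, as in real
multi-component ERPs.  Every epoch receives white noise, 1/f noise
(frequency-domain synthesis, global-variance normalized), common-mode 1/f
noise shared across channels, and rare large smooth transients
("artifacts").  All randomness derives from one seed through named child
streams (flash order, targets, each noise source), so sessions are
bit-reproducible and cohort members independently regenerable.  Epochs are
float32, the bundle payload format.

Presets (package choices; the source study prints no participant waveform
parameters, so these are tuned only to reproduce its qualitative group
pattern and say nothing about effect sizes in real data):

| preset | topography | components (µV, ms) | noise (white/pink/common, µV) |
|---|---|---|---|
| `typical` | broad, centro-parietal (spread 4) | N200 4 @ 200, P300 8 @ 350 | 3.5 / 6.5 / 2 |
| `mild_atypical` | narrower, left-shifted (spread 2) | N200 4, P300 7 | 3.75 / 8 / 2 |
| `severe_atypical` | narrow left ridge over C5–CP5, spread (0.7, 0.45) | N200 3.0 @ CP5, P300 3.25 @ C5 | 4 / 10 / 1.5 |

The severe preset's informative channels (topography weight ≥ 0.5: C5 and
CP5) are disjoint from the default-8 subset, its amplitudes are small and
its 1/f noise elevated.  Three design findings fixed this preset's shape:
a rank-1 topography (one template × weights) makes all but one informative
channel redundant to the classifier, so recovery of a multi-channel
planted set requires components with distinct topographies; white noise
feeds overfit-driven candidate wins in the greedy search while temporally
correlated 1/f noise suppresses them; and common-mode noise gives any
second channel generic cancellation value, diluting selection specificity.
`make_cohort` jitters preset parameters per subject (center ±0.25 grid
units, spread ±15%, amplitudes ±20%, noise ±10%) with independent derived
seeds, and returns lazy members (sessions regenerate on demand) so large
cohorts do not hold gigabytes of epochs simultaneously.

Realism gaps, stated plainly: no volume-conduction forward model (a
Gaussian topography stands in); no continuous EEG — epochs are simulated
independently although the real inter-flash interval (≈156–167 ms) is
shorter than the 800 ms window, so real epochs overlap and share noise;
no eye/muscle artifact structure beyond generic transients; stationary
noise within a session.  Passing cohort tests therefore demonstrates the
pipeline's behavior under controlled spatial/noise structure, not
performance on real EEG.

## Study-scale choices

The cohort studies run at sizes chosen for a desktop-class machine: 20
subjects for the severe and typical cohorts in the test suite (12 and 10
in the acceptance script), 30 calibration trials (matching the standard
calibration block), 60 trials for generalization subjects (40 calibration
+ 20 held out), and 200 noise-only subjects at 256 Hz on the 8 default
channels for the chance check (20 calibration + 20 test trials).  The
chance check scores held-out trials because resubstitution is biased (see
above); subjects whose noise session fails to calibrate are counted
separately and contribute no accuracy.

## Known limitations

* Resubstitution-based selection inherits selection bias; with ~30 trials
  the accuracy grid (multiples of 1/n) is coarse, so greedy steps tie
  often and the montage-order tie-break matters.  This is faithful to the
  method being studied, not an artifact to remove.
* The binomial improvement test conditions on the default arm's estimated
  success rate; it ignores the uncertainty in that estimate.
* The exact internals of the original calibration tool (its F-statistic
  bookkeeping and intercept handling) are not public; the classical
  stepwise-OLS construction documented above is used instead.
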