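# Methods

`playaffect` implements a non-obtrusive, user-tailored method for detecting
whether a player is bored or stressed during a gaming session, using only
signals that can be read off an ordinary video of the player's face: the
geometry of 68 tracked facial landmarks and the cardiac pulse recovered
from skin-color variation (remote photoplethysmography, rPPG). This note
documents the model, its tunable parameters, the synthetic-data generator
used to validate it, and the numerical and design choices that were
genuinely open.

## The method

**Signals and features.** Each recording is analysed with a moving window
of 15 s stepped by 1 s (93.33% overlap between consecutive windows). Per
window, up to nine features are computed:

| Feature | Definition | Aggregation |
|---|---|---|
| F1 mouth outer | perimeter of the outer-lip contour (landmarks 48–59) | mean |
| F2 mouth corner | distance between mouth corners 48–54 | mean |
| F3 eye area | summed shoelace area of the two eye polygons | std |
| F4 eyebrow | distance between inner brow points 21–22 | std |
| F5 face area | convex-hull area of all 68 landmarks | mean |
| F6 face motion | trailing 1 s path length of the nose tip (landmark 30) | std |
| F7 facial COM | per-frame displacement of the landmark centroid | std |
| F8 remote HR | mean heart rate from rPPG over the window | — |
| F9 sensor HR | mean of 1 Hz wrist-sensor samples in the window | — |

Slow-changing features (F1, F2, F5) are aggregated by the window mean;
fast-changing ones (F3, F4, F6, F7) by the population (n-denominator)
standard deviation. Landmarks use the iBUG-68 layout and raw pixel units;
scale effects are absorbed by per-subject feature standardization at
training time rather than by landmark-level normalization.

**rPPG chain (F8).** Per window, the three mean-RGB channels of the facial
region are linearly detrended and z-normalized, unmixed by FastICA into
three components, and each component's Hamming-windowed power spectrum is
computed with zero padding so the frequency-bin spacing is ≤ 1 bpm. The
component with the largest in-band (0.75–4 Hz, i.e. 45–240 bpm)
peak-to-total power ratio is taken as the pulse; HR = 60 × peak frequency.
A history constraint limits the change between consecutive estimates to
12 bpm: a larger jump falls back to the next-highest substantial in-band
peak, and failing that the previous estimate is carried forward, flagged
as not accepted. Windows with no estimate at all (degenerate signal, or
peak ratio below `min_peak_ratio = 0.05`) carry the last accepted value;
a leading run with no estimate is dropped from dataset assembly together
with its facial features, so emitted feature vectors are always complete.
The history is threaded across the *whole* recording's window grid —
including stretches later discarded from training — so the estimate can
track gradual heart-rate drift instead of seeing artificial jumps between
non-adjacent windows.

**Calibration segmentation and labels.** A calibration game ramps its
difficulty endlessly, moving every player from boredom to stress. The
first D = 45 s of each calibration recording are discarded as warm-up; the
remainder R is cut into thirds of L = floor(R/3) whole seconds. The first
third (H0) is labeled boredom, the last (H1) stress, and the middle is
discarded as emotionally ambiguous. Flooring keeps H0 and H1 equal length
and label-pure, with the slack left in the discarded middle. One training
sample is produced per 1 s window step inside H0 and H1, so training sets
are class-balanced per game by construction.

**User-tailored classifier.** Each subject gets their own
single-hidden-layer feed-forward network trained exclusively on that
subject's calibration samples. Hyperparameters — hidden units in
{2, 4, 8, 16, 32, 64}, L2 strength log-uniform in [1e−5, 1], constant
learning rate log-uniform in [1e−4, 1e−1] — are selected by random search
(30 draws by default) scored by mean ROC AUC over stratified 10-fold
cross-validation repeated 3 times, then refit on all training data.
Features are z-standardized inside the fitted pipeline, so scaling is
learned from training data only. Training runs a fixed epoch budget
(500) with early stopping off, so results are reproducible from the seed.

**Evaluation protocols.** Two protocols are implemented. Leave-one-
session-out cross-validation (LOSOCV) trains on two of the three
calibration games and tests on the held-out third, yielding fold
accuracies L1–L3 whose mean is the subject accuracy A_i; pooled fold
accuracies across subjects form the sample compared between feature-set
tests (MULTI_R, MULTI_G, FACE, HR_R, HR_G) with a Wilcoxon signed-rank
test. The cross-game protocol trains on all three calibration games and
tests on an independent evaluation game: per subject, self-reports (5-point
Likert ratings of stress and boredom per level) are turned into
antisymmetric scores stress = rstress − rboredom and boredom = −stress;
the two levels with the highest stress score and the two with the highest
boredom score are selected, levels whose relevant score is < 1 are excluded
as inconclusive, and feature vectors are sampled every 5 s (windows
[t−15, t) ending at t = 15, 20, 25, …). Ties among equal scores go to the
earliest-played level. A subject with no surviving level in either class
is unevaluable and excluded from the cohort mean with a logged reason.

**Chance level.** The minimal accuracy distinguishable from guessing on a
test set of size n is computed from the binomial cumulative distribution:
k_min is the smallest k with P(X ≤ k) ≥ 1 − α for X ~ Binomial(n, 1/c),
and the threshold is 100·k_min/n, also reported floored to an integer
percent (the convention of the chance-level literature this calibration
follows; n = 64, c = 2, α = 0.05 gives 60.94%, printed as 60%). A stricter
variant — smallest k whose own tail probability P(X ≥ k) is ≤ α — is
available via `convention="strict_tail"` (it gives 62.5% at n = 64).

**Wilcoxon signed-rank.** Authored rather than delegated because the
package needs an exact-distribution fallback that remains valid under
tied ranks plus the effect size r = |Z|/√N. Zero differences are dropped;
for N ≤ 15 the two-sided p comes from the exact sign-flip distribution
(computed by generating-polynomial convolution over doubled ranks); larger
N uses the tie-corrected normal approximation with continuity correction.
The implementation is cross-checked against `scipy.stats.wilcoxon` and
against exhaustive 2^N enumeration in the tests.

## Synthetic data generator

No public recordings exist for this task, so the generator synthesizes
complete sessions with the statistical structure the method assumes:

* **Heart rate** follows an Ornstein–Uhlenbeck process (mean-reversion
  0.2 s⁻¹, stationary SD 3 bpm) around a state mean: 65 bpm when bored,
  +20 bpm × effect size when stressed.
* **Pulse in RGB**: the waveform sin(2π∫f dt) + 0.3 × second harmonic is
  injected into the channels with green-dominant amplitudes
  (R:G:B = 0.3:1.0:0.6, master amplitude 1 pixel unit), atop a constant
  baseline, white noise (SD 0.3), and occasional step artifacts
  (rate 1/60 s⁻¹).
* **Landmarks** are a fixed synthetic neutral face template plus a
  mean-reverting rigid random walk (head motion, per-frame step 0.5 px
  bored, ×(1+effect) stressed), Poisson blinks (0.25 s⁻¹ bored,
  ×(1+effect) stressed) that collapse the eye contours over 300 ms, and
  Poisson mouth/brow events.
* **Sensor HR** samples the true trajectory at 1 Hz with ±1 bpm uniform
  jitter.
* **Study designs**: each subject plays 3 calibration sessions scheduled
  boredom→stress; a Study-2 subject additionally plays 7 evaluation levels
  of which levels 3 and 6 are designed stressful and 4 and 7 designed
  boring, with self-reports drawn consistently with the design (stressful:
  rstress ∈ {4,5}, rboredom ∈ {1,2}; conversely for boring; inconclusive
  equal ratings for the unconstrained levels). Subject heterogeneity:
  baseline HR jittered ±5 bpm, behavioural rates scaled by U(0.8, 1.2).

Everything is deterministic given the seed (per-subject streams spawned
from a master `SeedSequence`), and `simulate`d cohorts serialize to
byte-identical CSV/YAML directories across runs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: real landmark-detector noise and tracking
failures, illumination changes and skin-tone differences in the pulse
signal, emotional states that deviate from the elicitation schedule,
within-level mood fluctuation, and self-reports that misrepresent the
experienced state (a confusion probability exists but defaults to 0).
Synthetic separability between states is deliberately strong at effect 1;
real between-state effects are far subtler.

## Desk-scale study conditions

Cohort-level simulation studies (tests and the acceptance script) use
calibration sessions of 165 s (thirds of 40 s → 26 windows per segment,
156 training samples per class) and evaluation levels of 90 s (16 test
windows per level, ≈ 64 test samples per subject, matching the scale of
the method's chance-level calibration at n = 64), 10 subjects per cohort,
and a reduced search (4 random-search draws, 1×5-fold CV, 300 epochs,
`playaffect.pipeline.compact_model_config`). Per-subject deployment
defaults remain 30 draws with 3×10-fold CV.

## Numerical choices and edge cases

* Half-open time intervals [start, end) in seconds throughout; the window
  grid is anchored at the segment start.
* Population (ddof = 0) standard deviation for window aggregation; windows
  hold ≥ 750 frames at 50 fps, so the n vs n−1 distinction is negligible,
  but a single convention keeps exact tests meaningful.
* F6/F7 are 0 at frame 0 (no predecessor); F6's trailing 1 s window uses
  round(fps) displacement terms.
* Degenerate geometry (coincident or collinear landmarks) yields area and
  length 0 rather than an error; a convex hull of collinear points is 0.
* A zero-variance channel after detrending raises a degenerate-signal
  error in `condition_trace`; `estimate_hr_window` converts it into a
  no-estimate result.
* Metric conventions: macro averaging over the two classes;
  precision/recall/F1 are 0 when their denominator is empty.
* Whole-subject exclusion: one problematic calibration recording discards
  all of that subject's H0/H1 pairs.
* A level eligible for both test classes would join neither; the ≥ 1 score
  filter makes this unreachable, but the guard is kept.

## Known limitations

* The exact landmark-feature formulas are this package's fixed reference
  definitions; other plausible geometric proxies for the same muscles
  would differ in scale but monitor the same behaviour.
* The rPPG chain follows the blind-source-separation family (detrend →
  ICA → spectral peak with history constraint); chrominance-based methods
  are out of scope.
* Accuracy on synthetic cohorts is an upper bound driven by the simulated
  effect sizes, not a claim about real recordings; the original studies'
  headline numbers depend on recordings that are not publicly deposited.
* The networks are trained single-threaded at desk scale; no GPU or deep
  architectures.
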