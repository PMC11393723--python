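# Methods

This note documents the models, conventions and design choices behind
`smmkit`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

Stereotypical motor movements (SMMs) are rare events inside long
recordings: in annotated behavioral-assessment corpora they occupy a few
percent of the timeline, individual episodes average about 10 s with a
standard deviation comparable to the mean, and the recorded scene contains
the child plus one or more adults. The package operates downstream of pose
estimation and tracking: its input is a multi-person stream of 17-keypoint
COCO-layout skeletons with per-joint detection confidences at 30 fps.

Conventions fixed package-wide: COCO-17 joint order; 0-based frame indices;
half-open intervals `[start, end)` with frame membership decided by the
frame's start time; a keypoint with confidence 0 is missing and excluded
from all geometry.

## Child identification

Downstream analysis must use only the child's track. The module exposes a
pluggable per-frame scorer (`SkeletonFrame → probability`); the shipped
baseline is a logistic function of the standardized negative skeleton
height, `sigmoid((median_height − height) / scale)`, where the height is the
shoulder–ankle vertical extent and the median/scale (MAD × 1.4826) are
scene statistics over every tracked skeleton in the recording. This uses
the single most reliable untrained cue — preschool children are much
shorter than adults — and is intended to be replaced by a trained
child/adult image classifier where one is available (per-frame
probabilities can be supplied as CSV). Frame probabilities are mean-pooled
per track and the track with the highest mean wins, with ties broken toward
the lower person id. Track-level pooling (rather than per-frame switching)
reflects that one child identity should hold for a recording; how to
reconcile per-frame classifier output with tracker identity when they
disagree is genuinely open, and mean pooling is this package's choice.

## Window scorer baseline

The detection contract requires only a map from a 200-frame window of the
child track to a confidence in [0, 1]; a trained spatio-temporal network
can be plugged in as a callable. The shipped baseline is deliberately
interpretable and trainable on a desktop:

* **Normalization.** One offset per window (the window-mean mid-hip) and
  one scale (median shoulder–hip distance), so features are invariant to
  translation and uniform scaling but within-window motion is preserved.
  Centering per frame would cancel torso oscillations (body rocking) and is
  avoided.
* **Gap handling.** Occluded runs of ≤ 10 frames per joint are linearly
  interpolated; longer runs are zero-filled and counted in a flag feature.
* **Features.** Per joint: dominant oscillation frequency and the fraction
  of spectral power in 0.5–5 Hz (Hann periodogram, DC excluded), the
  velocity-autocorrelation peak over oscillation-scale lags, and an
  RMS-based displacement amplitude. Across joints: quantiles (25/50/75%)
  over frames of the per-frame band-limited motion envelope (3rd-order
  Butterworth band-pass, 0.5 s RMS smoothing, max over joints). The
  envelope quantiles are the key temporal-coverage features: they respond
  to *how much of the window* oscillates, not just how strongly.
* **Model.** Logistic regression (standardized features, L2, C = 1) on a
  10-dimensional aggregation (max/mean band fraction, max/mean
  autocorrelation peak, log amplitude, log envelope quantiles, dominant
  frequency of the strongest joint, mean confidence).

**Fractional training labels.** Training windows are taken around each
labeled segment at five offsets (0, ±¼, ±½ window) and labeled with the
fraction of window frames inside an SMM segment; sampled negative segments
contribute windows labeled 0 (fractional targets are fit by the standard
two-copy sample-weight expansion of the cross-entropy). This makes the
fitted score an estimate of the window's *SMM content* rather than a
saturated class probability. The distinction matters because of the
pipeline's aggregation semantics: every frame takes the maximum score over
the ~7 windows covering it, so if windows barely overlapping an episode
already score above threshold, each detected event is inflated by up to a
window width on both sides and frame-wise precision collapses. With
content-calibrated scores, a frame clears a high threshold only when some
covering window is mostly SMM, keeping detected boundaries close to the
truth. The residual geometry is a precision–recall trade-off inherent to
windowed max-aggregation: episodes shorter than roughly `θ·W` frames (≈5.7 s
at θ = 0.85, W = 200) can never reach the threshold and are missed, while
each detected episode still carries up to `(1 − θ)·W` frames of boundary
slack per side.

## Detection and quantification

Window starts are `0, stride, 2·stride, …` while `start + width ≤ n`; if
the last start stops short of the final frame one tail window is anchored
at `n − width` (recordings shorter than a window yield a single short
window). The threshold is inclusive (`≥ θ`) and no minimum event length is
imposed by default (a config option exists). Multi-camera assessments are
scored per camera; no cross-camera fusion is attempted. Per-assessment
burden: event count, events per minute, median event length (mean of the
middle two for even counts; 0 with a `no_events` flag for empty lists), and
percent time. Cohort tables use linear-interpolation quartiles — the
convention is pinned because IQRs of small cohorts depend on it.

## Evaluation machinery

* Frame-wise confusion counts partition all frames; precision, recall,
  specificity and NPV return NaN (flagged, never a crash) on empty
  denominators. Aggregation across assessments: pooled counts for the point
  estimate, mean ± 1.96·SEM of per-assessment values for the interval.
* Precision–recall sweeps re-run full event extraction per threshold, so
  points reflect the deployed pipeline, not raw thresholding.
* Lin's concordance correlation coefficient uses population (1/n) moments:
  `CCC = 2·cov / (var_x + var_y + (mean_x − mean_y)²)`; the sample/population
  choice moves third decimals and is therefore fixed. Bootstrap CIs
  resample assessment pairs, 1000 times, percentile method, seeded.
* Cohen's κ uses marginal-product chance agreement; κ is undefined (NaN)
  when both raters are constant and identical.
* The reannotation protocol samples an equal number of hits, false alarms,
  correct rejections and misses without replacement (seeded) and relabels
  by either-annotator union (logical OR), which can only increase the
  positive count.
* The 2×2 χ² applies the Yates continuity correction with clamping,
  `Σ max(|O − E| − 0.5, 0)² / E`. Clamping (not part of every
  implementation; scipy's is unclamped) is required for small-deviation
  tables and reproduces published cohort-comparison values; the
  implementation is cross-checked against scipy where the clamp is
  inactive. The pooled t uses `scipy.stats.ttest_ind_from_stats`; pooled t
  statistics computed from rounded group summaries can differ by a few
  hundredths from values computed on raw data. Mann–Whitney U uses scipy's
  asymptotic method (midrank ties, tie-corrected normal approximation).

## Synthetic data generator

The generator defines the study conditions under which the package is
exercised; its defaults emulate the annotated corpora this pipeline targets.

* **Scene.** `n_persons` skeletons from a canonical standing template;
  adult height 420 px (with ±5–10% variation), the child at
  `child_scale = 0.6`. The child's identity is drawn at random per seed so
  no stage can rely on a fixed id.
* **Background motion.** Whole-body mean-reverting (AR(1)/OU) drift with
  stationary SD 40 px and time constant 8 s — smooth, aperiodic, with power
  concentrated below the SMM band — plus small fast per-joint tracking
  jitter (1.5 px, 0.15 s).
* **Episodes.** Count = ⌊rate × minutes⌋ (rate default 0.2/min, which with
  the mean length gives ≈3.3% of the timeline in SMM, matching the sparse
  regime of annotated corpora). Lengths are lognormal, moment-matched to
  mean 9.89 s / SD 9.56 s — a printed SD comparable to the mean implies
  strong right skew, and the lognormal is a modeling choice (the true
  family is unknown). Placement is uniform without overlap. Each episode is
  a sinusoid with raised-cosine ramps on type-specific joints: wrist
  flapping 2–4 Hz, torso rocking 0.5–1.5 Hz (horizontal), whole-body
  jumping 1–3 Hz (vertical); amplitude 35 px (55 px in the easy preset).
* **Dropout.** Joints go missing (confidence 0) i.i.d. at 2% (0.5% easy).
* **Corpora.** Per-assessment SMM rates are drawn lognormally around the
  template rate with log-SD 0.96, matching the wide interquartile spread of
  per-child SMM rates in annotated cohorts, truncated so expected SMM time
  stays below 30% of the recording. Children are distinct; the split is by
  child. Assessments default to 10 minutes — long enough for ~600 windows
  and several episodes per recording while keeping a 30-assessment
  experiment in the minutes range on one CPU; annotated clinical
  assessments are ~40 minutes, and nothing in the pipeline depends on the
  difference.

**What the generator does not model** — and hence what passing tests do not
show about real data: pose-estimator identity switches and track
fragmentation, camera changes and multi-camera views, correlated occlusion
(dropout is i.i.d.), non-sinusoidal and irregular SMM waveforms, SMM-like
periodic adult motion (available only via the adversarial flag), and
annotator disagreement about boundaries. End-to-end accuracy on this
corpus is a functional check of the pipeline's machinery under conditions
where the signal is knowable, not a forecast of clinical accuracy.

## Numerical and degenerate-input choices

* Windows with under 50% of frames having ≥ 8 visible joints raise a
  low-visibility error in feature extraction; during sliding-window scoring
  such windows score 0 (treated as confidently non-SMM).
* Torso scale falls back to 1 when no shoulder–hip pair is measurable.
* Negative-segment sampling is rejection sampling (≤ 1000 attempts per
  segment) with lengths resampled from the positive empirical distribution;
  exhaustion raises a capacity error carrying the partial sample. Corpus
  training-set construction keeps the partial sample.
* Greedy descending-IoU box–skeleton matching (ties toward the lower box
  index) rather than optimal assignment: deterministic, O(n² log n), and
  equivalent in the near-diagonal scenes it is used for.
* Training is deterministic given seed and input order (L-BFGS on a convex
  objective from a fixed start); models serialize to versioned JSON.

## Known limitations

The baseline scorer detects periodicity, so aperiodic SMMs and SMMs
shorter than ~θ·W frames are outside its reach; event onset/offset
accuracy is not evaluated (only frame-wise overlap and per-assessment
burden); no SMM-type classification is attempted; severity measures beyond
count/rate/duration are not provided.
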