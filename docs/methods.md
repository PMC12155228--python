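# Methods

`ethophys` implements the analysis chain of a trial-structured
social-exclusion experiment in mice: a cued task (60 trials per session, 10 s
cue, 15 s transparent-barrier window, inter-trial intervals jittered over
40–60 s) with three conditions — Social Exclusion (SE), One Mouse (OM), Tone
Only (TO) — recorded simultaneously with overhead video (30 fps, 9-point
pose skeleton), two-channel fiber photometry (20 Hz), and cellular-resolution
calcium imaging (10 Hz ΔF/F0).  This note documents the models, the defaults
that matter, what the synthetic data does and does not emulate, and the open
design choices we resolved.

## Time and coordinate conventions

Seconds everywhere; per trial the cue onset is t = 0 and every window is
half-open `[start, end)` — the sample containing the onset is the first
post-onset sample.  This removes any boundary-sample ambiguity; a window of
`pre + post` seconds at rate `fs` always holds `round((pre+post)·fs)`
samples.  Coordinates use the image convention (origin top-left, y down, px).
Missing keypoints travel as NaN and are resolved exactly once, in
`features.preprocess_track` (linear interpolation of interior gaps, edge
extension, then a centered moving average — default window 5 frames; the
original smoothing window is not recoverable from the source material, so it
is a config key).

## Kinematic features

The per-frame feature set: distance and unsigned angle to the reward port,
body velocity and acceleration (backward differences, causal; first frame
0), head–body and head–tail orientation, signed turning angle wrapped to
(−180°, 180°], tortuosity over trailing 1 s and 5 s windows (path length /
net displacement; when net displacement < 1 px the ratio is taken against
1 px and capped at 50, so a stationary animal is maximally tortuous rather
than undefined), nose–tail distance and its derivative, arena zone, and the
discrete flags touching-barrier (nose within `contact_eps` = 15 px of the
barrier segment), oriented-to-port (angle < 45°) and their conjunction.
Continuous features are z-scored over the whole session (per-session rather
than per-trial — the source material does not specify; per-session preserves
cross-trial amplitude differences), discrete flags pass through, and trials
are cut to `[0, 15 s)` windows.

Zones default to three vertical bands on the subject's side of the barrier
(near / middle / far); the chamber geometry is configurable as arbitrary
polygons.  A "huddle quality" column can be passed through from external
scoring but is never computed: it would require the other animals'
positions, which this pipeline does not track.

## Behavioral structure

**Embedding.** UMAP (neighbors 15, min_dist 0.1, 2-D) over trial-windowed
feature rows, DBSCAN (eps 0.5, min_samples 10) on the embedding; noise = −1.
Hyperparameters are config keys — no values are inherited from the source
analyses, which reported none.  New frames map onto a frozen embedding
(`transform`) and take the nearest cluster within eps, so detector calls and
HMM states can be overlaid on one behavioral map.  Clusters are labeled
Attending either from a manual list or by rule: mean barrier-contact
evidence > θ (default 0.5, strict).

**State HMM.** Behavior syllables (categorical, alphabet taken from the
data), discrete flags (Bernoulli) and continuous features (diagonal
Gaussian) are modeled as conditionally independent given a hidden state;
EM with scaled forward–backward (numba-accelerated), k-means-seeded
Gaussian means, probability floors of 1e-6, variance floor 1e-4, restart on
a zero-occupancy state.  Model selection scans K = 2..12 and takes the elbow
of the log-likelihood curve, defined scale-free as the interior K whose
marginal gain most dominates the following gain (a raw second difference
peaks one K early whenever successive pre-elbow gains span orders of
magnitude); a user override is provided, since the source analysis reports
choosing 4 states from a 2–12 scan without naming a criterion.  Decoding defaults to posterior argmax (Viterbi by
flag).  Stickiness is the maximum-likelihood self-transition estimate
#(s→s)/#(transitions leaving s); mean dwell is the mean run length.

## Behavior detection (heatmap regression)

The detector regresses one sigmoid heatmap per behavior class from a single
grayscale frame; peaks after k×k non-maximum suppression (default k = 5,
τ = 0.5) are behavior instances, the heatmap value at the peak is the
confidence (never rescaled), and a frame is positive iff ≥ 1 peak survives.
Targets are pixelwise maxima of unit-peak Gaussians (σ = 0.05·min(H,W) at
output scale, stride 4) centered at point labels.  NMS resolves plateaus by
keeping the lexicographically smallest (row, col) of each connected
component of qualifying pixels.

The network is authored in numpy: two 5×5 conv + ReLU + 2×2 max-pool
stages (8 and 16 channels) and a 3×3 output conv at stride 4, trained with
positively-weighted pixelwise binary cross-entropy (pos-weight 8; focal
variant by config) under Adam (lr 3e-3).  Pure numpy, single-threaded, so
training is bit-deterministic for a fixed seed.  A ResNet-scale backbone is
out of scope for this package; the small stack is the supported profile and
reaches F1 = 1.0 on the synthetic fixture.

Trial quantification: baseline B = attending-frame count in [−5, 0) s;
ΔA_i = count_i − B for the three post-cue 5 s bins, total ΔAttending =
ΣΔA_i.  Subtraction (not ratio) is used per bin so the bin sum is
well-defined when B = 0.  Trial classification thresholds at the median of
the pooled counts (global mode) or the animal's own counts (local mode),
strictly; top/bottom-15 selection breaks ties by trial order.

## Fiber photometry

Causal (trailing-window) median filter, span 200 ms, on both channels —
"forward only" is read as using no future samples.  The reference channel is
regressed out of the signal channel with slope/intercept fit by least
squares on the **trial-averaged** sample pairs of the −1..0 s pre-cue window
only (so stimulus-evoked transients cannot bias the fit), then applied to
the full traces.  Each trial is z-scored against its own −1..0 s baseline;
zero-SD baselines are excluded, > 50% exclusions reject the session.
Trial summaries are trapezoidal AUCs over sensor windows (0–20 s for
dopamine/oxytocin sensors, 0–15 s for the endocannabinoid sensor).

Decoding pools individual timepoints of a decode window across trials
(features: z value and time-bin index), trains a random forest (500 trees
default) with trial-grouped stratified folds — all timepoints of a trial
stay in one fold, which is what keeps a label-shuffled session at chance —
and reports pooled ROC-AUC plus a trial-level label-shuffle control.

## Calcium ensembles

PSTHs span −5..15 s at 10 Hz (200 bins); each trial is z-scored against its
own baseline, by default −1..0 s (the explicit normalization window of the
clustering analysis; −5..0 is a config option, and is what the oxytocin
figure used), then trials are averaged with optional fixed-seed count
matching across event types.  Responsiveness is a paired Wilcoxon
signed-rank of per-trial means, 5 s baseline vs first 5 s post-event, at
α = 0.05 per neuron uncorrected (a Benjamini–Hochberg switch exists, off by
default, matching the original analysis); significant neurons are signed by
mean z over the 15 s response window; < 6 trials → "none", flagged (the
signed-rank test cannot reach p < 0.05 two-sided below n = 6).

Profiles concatenated across event types are clustered with Ward linkage on
1 − Pearson correlation distances, cut at 30% of the maximum linkage
height.  Ward formally presumes squared Euclidean distances; linkage on the
precomputed correlation-distance matrix reproduces the common
statistical-toolbox behavior this analysis family uses, and a Euclidean
switch is provided for the rigorous variant.  Constant profiles (undefined
correlation) are excluded with label −1.  Downstream tables: per-condition
cluster percentages (each condition sums to 100), per-neuron
excitation/inhibition codes across event types (e.g. `A+NA0P+`) with
chi-squared comparison of code proportions across conditions, and
source→target flow counts for alluvial plots.

## Population decoding and trajectories

A single global PCA is fitted on trial-averaged activity (observations =
condition × time bins, variables = neurons) built **only from training-fold
trials**, refit per fold; the component count is the smallest reaching 90%
cumulative variance.  Single trials are projected with the fixed per-neuron
coefficients, and per time bin a classifier — logistic regression with L2
(the "GLM"), linear SVM, or random forest — is trained on the training
trials' PC features.  Multiclass problems run one-vs-all; unbalanced classes
are handled by repeatedly subsampling the majority to the minority size
(enough draws to cover all majority trials) and averaging test scores;
controls shuffle training labels only.  Everything fitted on a split is
hashed into a checksum, so the no-leakage property (corrupting held-out
trials changes nothing fitted) is directly assertable.  Rank decoding (tube
test: dominant / intermediate / subordinate, rank = win proportion) uses the
same machinery at 10 folds.

Trajectories are mean activity projected into the fixed PC basis and
averaged into ~100 time bins; geodesic length sums Euclidean distances of
adjacent bins ("adjacent timepoints" is read as adjacent bins of a ~100-bin
discretization; the bin count is a config key), separation is the bin-by-bin
Euclidean distance, and leave-one-animal-out drops all of one animal's
neurons while keeping the fitted coefficients — exactly one metric value per
animal.  Quantification uses the 90%-variance components, not the 2–3
plotted; smoothing applies only to plot exports.

## Synthetic data

The generators produce every pipeline input with planted truth, as pure
functions of (config, seed) with independent substreams per component.

* **Behavior**: a sticky Markov chain (default 4 states, self-transition
  0.98) drives a mean-reverting walk toward state anchors; the attending
  state anchors at the barrier with heading toward the port; the remaining
  skeleton rides on the torso in body-frame offsets.  A per-trial attending
  probability optionally biases the chain into/out of the attending state
  during cue windows.
* **Frames**: 64×64 grayscale, a Gaussian blob at the torso plus a faint
  barrier edge; attending frames render an elongated (rearing) blob with a
  point label at the nose.  The posture difference is what makes the class
  visible to a translation-equivariant detector — matching the premise that
  static image features suffice for single-image behavior detection.
* **Photometry**: shared motion artifact (Gaussian-smoothed noise,
  τ = 0.15 s, sd 2.5) entering the reference at unit gain and the signal at
  0.8; exponential bleach in the signal; trial-locked transients (rise
  0.5 s, decay 8 s) whose mean amplitude differs by Δ z-units between trial
  classes.  The artifact is fast and large relative to the noise floor
  (sd 0.05) because the −1..0 s regression fit only identifies the slope
  from variance *inside* 1 s windows: a slow, weak artifact would make the
  quoted procedure ill-posed on any data.  The transient decay matches
  slow neuromodulator-sensor kinetics (the reason sensor AUC windows extend
  to 15–20 s); amplitudes are expressed in units of the post-regression
  baseline noise so planted Δ is directly a z-scale effect.
* **Calcium**: neurons are drawn from archetype templates (per-event-type
  amplitudes in noise-SD units, shared rise/decay kernel) plus iid Gaussian
  noise, on one interleaved event timeline per session; animal identity and
  identity co-registration across conditions are recorded for LOO and
  overlap analyses.

What the generators do **not** emulate: photorealistic appearance, occlusion
and tracking errors, biophysical sensor/indicator kinetics, correlated
neural noise, slow drifts in behavior, or across-animal heterogeneity beyond
seed variation.  Passing tests therefore demonstrate algorithmic
correctness and calibration on data with known structure — not performance
on real recordings.

## Benchmark problem sizes

The end-to-end benchmarks (`ethophys.benchmarks`, re-run by
`scripts/acceptance.py`) use: 100 random 64×64 heatmaps for the NMS oracle;
200 training + 100 held-out detector frames; 20 replicates × 3 groups × 10
animals × 20-trial sessions (ITI 24–30 s) for the ΔAttending ordering; 20
replicates of 50 000-frame 4-state chains for HMM recovery; 100 000 frames
for stickiness; 24-trial sessions for photometry separation; 50 null seeds
of 20-trial sessions plus two full 60-trial sessions at Δ = ±3 (random
forest at 100 trees in this loop) for decoding calibration; 1000 null + 200
planted neurons × 15 trials for responsiveness; 120 neurons across 4
animals for clustering recovery; 50 shuffle seeds for the leakage guard.
These sizes keep each benchmark in seconds-to-minutes on one CPU while
leaving the statistical targets comfortably resolvable.

## Known limitations

* The detector supports the small-stack profile only; there is no GPU path
  and no large-backbone implementation.
* The HMM assumes conditional independence of syllables, flags, and
  features given the state, with diagonal Gaussian emissions.
* UMAP's `transform` for new data is approximate; cluster assignment of new
  frames uses nearest-neighbor-within-eps rather than re-running DBSCAN.
* `huddle_quality` and any multi-animal social geometry are out of scope.
* Ward-on-correlation-distance is kept for fidelity to the original
  toolbox behavior despite its formal mismatch with Ward's Euclidean
  assumption.
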