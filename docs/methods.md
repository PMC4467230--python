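# Methods

## The problem

During masked visual localization, a target appears at one of eight
circularly arranged positions and the observer both localizes it
(8-alternative forced choice) and reports whether they saw it.  Near the
visibility threshold this yields the minimal contrast for conscious
access: *seen-correct* and *unseen-correct* trials with identical
stimuli and identical (correct) responses, differing only in subjective
report.  Unseen localization far above the 1/8 guessing rate is the
blindsight regime.  The package asks *when* and *in what format* the
brain encodes target location in the two cases, using time-resolved
multivariate decoding of MEG/EEG epochs.

## Decoding model

Epochs are a `trials x channels x time` tensor.  Each channel is
divided by the standard deviation of its baseline samples pooled across
all trials (no mean subtraction — the normalization's job is to make
magnetometer, gradiometer and EEG units commensurable; a `demean` flag
exists but defaults off).  At every time sample an independent linear
SVM (cost C = 1, no hyperparameter search) is trained on the
single-sample channel vector under 15-fold cross-validation, and emits
a **calibrated posterior probability** per class via sigmoid (Platt)
calibration fitted on internal cross-validated decision values
(`CalibratedClassifierCV(SVC(kernel='linear', C=1), method='sigmoid',
ensemble=False)`).  Decoding curves are the mean posterior assigned to
the *true* class; chance is 1/8 for the location decoder and 1/2 for
the hemifield decoder.  Numerical choices: the internal calibration
split is 3-fold (seeded per fold and time sample, so reruns are
bitwise reproducible), SVC `tol` is 1e-2 (linear kernel on z-scored
features; tightening it changes posteriors at the fourth decimal while
tripling runtime), multiclass probabilities use scikit-learn's
one-vs-rest sigmoid renormalization rather than libsvm's pairwise
coupling (differences at the third decimal), and argmax readouts break
ties toward the lowest class index.

Derived statistics:

* **Distance profile** — posterior mass as a function of circular
  distance (0–4 steps of 45°) between decoded and true location, the
  two symmetric neighbours pooled per bin; uniform posteriors give
  (.125, .25, .25, .25, .125).
* **Chance correction** — among unseen-correct trials an estimated
  `g/K` (with `g = n_incorrect · K/(K−1)`, K = 8) are lucky guesses
  assumed to carry incorrect-trial-level information; the informed-trial
  mean is `(n_c·S_c − (g/K)·S_i)/(n_c − g/K)`.  The estimator is
  validated by parameter recovery on simulated mixtures.
* **Window statistics** — per-stage means across replicates with
  one-sample t against chance and paired condition contrasts
  (one-tailed only when flagged).

## Cross-condition generalization

The asymmetry test trains the binary hemifield decoder on one
visibility condition (its own 15 folds) and evaluates each fold's model
on (a) the held-out fold and (b) every trial of the other condition,
averaging (b) over folds.  Trials are first balanced over hemifield ×
visibility by seeded subsampling without replacement.  Identical
train/test masks are treated as self-transfer (the transfer curve *is*
the within curve); partially overlapping conditions are an error.
Transfer at a time t' is evaluated with the same model (same held-out
fold) used at the training time t, so no test trial ever influences the
model scoring it.

## Temporal generalization and Classification Endurance

A decoder trained at t is tested at every t'; the matrix shares folds
and per-(fold, t) seeds with the plain decoder, so its diagonal equals
the standard decoding curve bitwise.  **Classification Endurance (CE)**
is the decoder half-life: at training time t with diagonal excess
`e(t) = M[t,t] − chance > 0`, forward CE is the largest n such that
`M[t, t+i] − chance ≥ 0.5·e(t)` for *all* 1 ≤ i ≤ n (backward is the
mirror).  Two deliberate choices:

* CE is measured on the **above-chance excess**, not the raw
  probability: half of a raw 8-class probability (e.g. 0.5 × 0.157 =
  0.078) is below the 0.125 chance level, which would make a raw-level
  half-life infinite; the excess-based definition is the only
  self-consistent reading.
* The run must be **contiguous from lag 1**: an isolated sub-threshold
  dip terminates it (the stricter, more reproducible convention).

Training times whose diagonal is at or below chance have *undefined*
(NaN) CE, not zero.  CE is summarized per replicate in 5 equal
half-open timeframes of the late window (272–800 ms by default) and
submitted to a repeated-measures Visibility × Direction × Timeframe
ANOVA (statsmodels `AnovaRM`) with two planned contrasts (forward and
backward seen-vs-unseen paired t).  CE is computed per replicate and
then averaged; computing it on the replicate-averaged matrix is also
possible by passing that matrix directly.

## Evoked statistics

Global field power is the across-channel SD of the evoked response per
sample; component windows default to the two highest GFP lobes after
150 ms with user-set widths (36 ms and 300 ms, the canonical N2-like
and P3-like windows).  Condition contrasts use a paired cluster-based
permutation test: per-(channel, sample) paired t, two-tailed
cluster-forming threshold at p < 0.05, spatio-temporal clusters via
channel adjacency plus temporal contiguity, cluster mass = sum of t,
and a max-statistic null from sign-flipping replicate differences:
`p = (1 + #{null ≥ observed})/(1 + n_perm)`.  Synthetic channel
adjacency is a symmetric 4-nearest-neighbour graph on seeded random
2-D sensor positions (bridged if disconnected); real layouts can be
supplied as any sparse adjacency.

## Staircase calibration

Mask contrast (0–255 intensity) starts at 230 and is adjusted per
block by `step = max_step · (p_seen − 0.5)/0.5`, so all-seen or
all-unseen blocks move the full current maximum (80 initially).  The
published constraints fix only the boundary behaviour; the linear step
law and the geometric max-step decay (× 0.7 per completed block) are
our admissible reading, both config-exposed.  Block sizes follow
4, 4, 6, 8, then 10; stopping occurs when |step| < 1.5 or after 80
trials.  A trial is 'Seen' if reported seen and localized correctly, or
reported seen, mislocalized, and the error was detected (the observer
model's `p_error_detect`, default 1).  Higher intensity = stronger mask
= fewer seen trials; the controller drives p(seen) to 0.5.  Simulated
steep observers recover their threshold to within a few intensity
units.

## The synthetic world

`SignalRecipe` states the world the analysis assumes; its defaults are
the stated experimental conditions (64 Hz, epochs −500…+2000 ms, stage
windows 0–115 / 115–162 / 162–271 / 271–800 ms, early peak at 147 ms):

* **Stage 1** — no location information.
* **Stage 2** — a location-specific unit-norm Gaussian spatial pattern
  ramps from the stage onset to the 147 ms peak.
* **Stage 3** — the same pattern at 0.75 of peak amplitude.
* **Stage 4, unseen trials** — the stage-3 pattern lingers, decaying
  exponentially with τ = 550 ms.  τ is not stated anywhere; it was set
  so the lingering code's decoder half-life (τ·ln 2 ≈ 381 ms) matches
  the magnitude of the reported unseen forward CE (~382 ms).
* **Stage 4, seen trials** — a chain of `chain_states` (default 4)
  *mutually orthogonal* location-specific codes, each active for
  `state_duration_ms` and amplified by `seen_gain` (default 2), **plus**
  the same unamplified lingering code (`linger_on_seen`, default on).
  The subset relation — unseen codes ⊂ seen codes — is what produces
  the asymmetric generalization: an unseen-trained decoder reads the
  lingering code, present in both conditions; a seen-trained decoder
  weights the amplified chain codes, absent on unseen trials.

An optional **ignition component** (`ignition_amplitude`, default 0 =
off) adds a location-*independent* unit-norm spatial pattern to seen
trials only, with a raised-cosine envelope over 280–600 ms.  The
location codes average out across the eight positions, so without it
the trial-averaged seen vs unseen contrast has no mean-field
difference; the ignition component emulates the generic late (P3-like)
conscious-access response that the evoked cluster statistics target.
It is drawn from a separate seed stream, so enabling it perturbs
neither the location patterns nor the noise of a given seed.

`state_duration_ms` defaults to the stage-4 span divided by
`chain_states` (132.25 ms at the default windows); an explicit duration
whose chain overflows the stage is a configuration error.
`pattern_snr` (peak pattern amplitude over the unit per-channel noise
SD, default 1) was chosen once so that desk-scale runs produce 8-class
decoding probabilities in the empirically realistic 0.13–0.17 range.
Unseen-incorrect trials carry a separate SNR multiplier (default 1 — we
do not assume their stimulus-locked signal is weaker, only that they
guessed).  EOG channels never carry location signal.  ROI variants gate
all signal envelopes by a per-region onset latency and apply the
stage-4 amplification only in workspace regions (superior parietal,
superior frontal).

The behavioral observer has a logistic visibility psychometric in mask
contrast (p(seen) = 0.5 at threshold; the published procedure states
only the 50% target, not the functional form) and localization accuracy
0.866 (seen) / 0.507 (unseen, the blindsight regime); incorrect
responses are uniform over the 7 remaining locations, and a
`guess_uniform` mode forces exact 1/8 accuracy.

**What the generator does *not* emulate** — and hence what a green test
does not establish: noise is i.i.d. Gaussian per channel-sample (no 1/f
spectrum, no spatial noise correlations, no artifacts), sensors have no
realistic geometry or forward model, stage transitions are hard-edged,
and behavior and signal are conditionally independent given the trial
labels.  Tests establish that the pipeline recovers the stated
structure from data that contain it, at correctly calibrated error
rates — not that real cortex behaves this way.

## Degenerate inputs and tie-breaks

Zero baseline SD names the offending channel and aborts.  A class
missing from any training fold-complement aborts with advice to
rebalance.  Zero-variance window statistics report t = ±inf with p → 0
and a warning (or t = 0, p = 1 when the difference is exactly zero).
A zero-variance CE table reports all F = 0, p = 1 ("no effect") rather
than failing.  Empty balancing cells list the missing cell.  Windows
are half-open `[a, b)` everywhere, with samples assigned to the earlier
window at edges.

## Known limitations

* Calibration differs from libsvm's internal pairwise-coupling Platt
  procedure at roughly the third decimal; all chance-level and
  asymmetry results are insensitive to this.
* The fold count for the visibility decoder defaults to 10 (location:
  15); both are parameters.
* Cluster tests run per channel type when called that way by the
  pipeline; pooled-type testing is not offered.
* The staircase's step-decay schedule is one admissible reading of a
  qualitatively described procedure.
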