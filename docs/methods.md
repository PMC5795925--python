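# Methods

## Signal model and conventions

The package operates on uniformly sampled tri-axial accelerometer streams in
units of g (1 g = g0 = 9.81 m/s², configurable). Samples are 0-based, every
range is half-open `[start, end)` in sample indices, and a duration `d`
seconds is quantized as `round(d·fs)` samples. The per-sample acceleration
vector magnitude is `avm = sqrt(ax² + ay² + az²)`; at quiet rest `avm ≈ 1 g`
regardless of device orientation, below 1 g during free fall, and well above
1 g at impact.

A fall is modeled as three consecutive stages: **pre-impact** (a brief
free-fall dip below 1 g as balance is lost), **impact** (a burst of one or
more supra-threshold peaks; the highest is taken as the moment of ground
contact), and **post-impact** (low-variance lying). The segmentation task is
to anchor fixed-duration stage windows on the correct (highest) impact peak,
which is non-trivial when a burst contains several peaks.

## Event-triggered segmenter

The segmenter is a four-state machine that consumes one sample at a time and
stores at most `round((t_pre + t_mp + t_sg)·fs)` samples (a ring buffer), so
it is suitable for online, memory-bounded use.

Parameters (defaults):

| parameter | default | unit | role |
|---|---|---|---|
| `tau` | 1.8 | g | peak threshold; a *peak* is any sample with `avm > tau` (strictly; no local-maximum requirement) |
| `t_pre` | 1 | s | pre-impact window, ending at the peak |
| `t_mp` | 1 | s | impact window, starting at the peak; also the multi-peak countdown |
| `t_sg` | 1 | s | post-impact (sample-gathering) window |
| `fs` | 100 | Hz | sampling rate |

The 1-s stage windows and the 1.8 g threshold are the operating point at
which stage-aligned classification performs best on chest-worn laboratory
fall corpora; all four are configurable.

Numerical and tie-break choices, fixed here as the normative behavior:

* **Peak re-anchoring.** In multi-peak detection a strictly higher sample
  re-anchors the recorded peak and restarts the countdown in full, so the
  impact stage always spans exactly `t_mp` from the final recorded peak.
  The higher-peak check precedes countdown expiry: a strictly higher sample
  arriving on the very sample where the countdown would expire still
  re-anchors (the re-anchoring window is `(peak, peak + t_mp]`, inclusive of
  the expiry sample). Ties between equal avm values keep the earlier sample.
* **Carry-over timer.** A supra-threshold sample seen during sample
  gathering is remembered as a temporary peak (the running maximum; it needs
  only to exceed `tau`, not the emitted segment's peak). After emission the
  machine re-enters multi-peak detection anchored on it, with the countdown
  set to `t_mp` minus the time already elapsed since that peak — the only
  reading that keeps the next impact stage anchored exactly `t_mp` after its
  peak. A non-positive remainder (possible only when `t_sg` exceeds `t_mp`)
  skips directly to sample gathering, truncated so emission still happens on
  the last post-stage sample; samples already consumed by the previous
  gathering window are not re-scanned for temporary peaks.
* **Boundary conditions.** Peak detection begins only after the initial
  buffer of `t_pre` seconds, so a full pre-impact window always exists. A
  trailing event whose post window runs past stream end is dropped, never
  padded. A stream whose maximum avm never exceeds `tau` emits nothing.

An offline reference implementation (`oracle_segment_stream`) computes the
same output by direct scanning over the precomputed avm series; the
streaming and offline routes are checked for exact segment-list equality on
hundreds of randomized synthetic streams.

## Features

Nine features per stage, 27 per segment, computed over the stage's avm
series `a_i` (`n` samples, `dt = 1/fs`): min, max, mean (g); velocity
`Σ(a_i − 1)·g0·dt` (m/s, signed — the gravity-compensated integral of avm,
used because the true vertical axis is unknown from a single accelerometer);
energy `Σ a_i²·dt` (g²·s); population variance (g²; population rather than
sample variance avoids the n−1 edge case at n = 1); RMS `sqrt(mean(a_i²))`
(g); EMA, the final value of `e_i = α·a_i + (1−α)·e_{i−1}` with
`α = 2/(n_ema+1)` and a 0.5 s span `n_ema = round(0.5·fs)` (g); and SMA
`mean(|ax_i| + |ay_i| + |az_i|)` (g). The exact smoothing span for the EMA
and the velocity reference are configuration choices; the defaults above
follow the common forms in the activity-recognition literature.

Sliding-window baselines featurize whole windows without stage alignment
(9 values; a 27-value thirds-split variant exists but is not the default) —
stage blindness is precisely what those baselines are being compared for.

## Baselines

* **FNSW / FOSW**: fixed windows `[kW, (k+1)W)` resp. step
  `max(1, round(W·(1−overlap)))`; counts follow the closed forms
  `floor(L/W)` and `floor((L−W)/step)+1`. The window length is W = 3 s
  (= `t_pre+t_mp+t_sg`) by default so every method sees equal-duration
  evidence; the overlap grid used in evaluation is 25/50/75/90 %.
* **CCA**: 2-s non-overlapping trigger windows with a 1.6 g threshold; on
  trigger, the window's highest sample anchors 1 s of pre-impact and an
  11-s tail (1 s impact + 10 s post, mirroring the event segmenter's
  impact duration for comparability). No multi-peak re-anchoring: a higher
  peak outside the trigger window is missed — the deficiency the event
  segmenter corrects. Segments whose pre or impact span would leave the
  stream are dropped; the post tail is clipped at stream end.
* **IMPACT+POSTURE**: per-sample triggers on SVtot (= avm), SVD (magnitude
  of the 0.25 Hz first-order high-pass-filtered axes), SVmaxmin (max−min of
  SVtot over a trailing 0.1 s window) and Z2 (= `(SVtot²−SVD²−1)/2`),
  followed by a posture check: mean |vertical acceleration| < 0.5 g over a
  2-s window starting 2 s after the trigger. The SVD/SVmaxmin/Z2 formulas,
  filter constants and posture timing are reconstructions of the classical
  threshold-detector design and are all configurable. Trigger thresholds are
  fitted per training fold: candidates are deciles of each parameter's
  per-sequence maxima, searched exhaustively for the joint set maximizing
  training F-score, ties broken toward lower thresholds (favoring recall).
  This deterministic grid search replaces the box-plot analysis of the
  original design, which is not algorithmically specified, while optimizing
  the same objective.

## Evaluation protocol

Binary sequence-level classification under leave-one-subject-out
cross-validation: per fold, a classifier is trained on all segments from the
other subjects and applied to the held-out subject; a sequence is a detected
fall when at least one of its segments is classified as a fall (TP/FP/FN/TN
by the sequence's annotation; the four outcomes partition the dataset).
Precision, recall and F-score are computed from the counts, with
zero-denominator cases reported as an explicit undefined marker. Per-activity
false positive / false negative ratios are `FP_i/p_i` and `FN_i/q_i`.

Training labels for segments are derived by overlap: a segment of a fall
sequence is labeled fall when its evaluation range (impact range for stage
segments, whole window for sliding windows) overlaps the annotated event
region (any overlap by default; a minimum-overlap fraction is configurable).
Some such rule is required to train on sliding windows; it is stated
explicitly because different rules shift baseline performance.

Classifiers are scikit-learn estimators with fixed hyperparameters: CART
(decision tree), k-NN (k = 3, Euclidean, uniform weights), logistic
regression (C = 1e9), linear-kernel SVM. Features are z-scored with
training-fold statistics for k-NN/LR/SVM; the tree sees raw features.
Computational cost is accounted as the number of segments produced — equal
to the number of feature-extraction invocations — per subject; wall-clock
time may be recorded but is never asserted.

Paired per-subject scores are compared with a two-sided Wilcoxon signed-rank
test (α = 0.05): zero differences dropped, the null distribution enumerated
exactly for ≤ 12 remaining pairs and normally approximated (tie-corrected,
no continuity correction) above.

## Synthetic data generator

The generator emulates the *structure* of laboratory fall corpora, not their
biomechanics. Defaults: 10 subjects, 4 falls and 8 ADLs (2 walking,
1 standing, 1 sitting, 1 lying, 2 near-falls, 1 sitting-on-floor) per
subject, 100 Hz. Falls are piecewise half-sine/constant envelopes on the
gravity axis: 2–3 s standing, a free-fall dip to 0.2–0.7 g lasting
0.2–0.5 s, an impact burst of 1–4 pulses with the highest (2.3–5.5 g) last
and earlier pulses at least 0.3 g lower, then ≥ 2 s of lying during which
gravity moves to a horizontal axis (so posture checks work). Inter-peak gaps
are drawn from [0.05, 0.4] s but capped so the whole burst spans less than
one impact window — this makes the highest peak reachable by re-anchoring in
every generated fall, i.e. correct alignment is a structural property of the
data, matching the premise that all impact peaks of one fall belong to one
impact event. Near-falls are an isolated 2.0–2.5 g pulse on a standing
baseline with no dip and no lying. Quiet ADLs stay within [0.4, 1.7] g.
Axis noise is independent Gaussian with sd 0.02 g, clipped at ±3 sd so the
generator's amplitude invariants hold deterministically rather than with
high probability. All amplitude defaults are the implementer's choices —
real corpora publish only the stage semantics and the supra-1.8 g impact
minimum — and are recorded in `GeneratorConfig`.

Randomness: one root seed; each (subject, sequence) pair derives an
independent substream via `numpy` `SeedSequence` counter splitting, so
generation is reproducible and order-independent. Per-subject amplitude and
timing multipliers (±10 %) add inter-subject variation.

**What passing tests show, and what they do not.** The synthetic classes are
far better separated than real chest- or waist-worn recordings: there is no
sensor drift, no unconstrained daily activity, no protective-action peaks in
the pre-impact stage, and near-falls differ from falls exactly and only in
the modeled structure. Perfect or near-perfect synthetic LOSO scores
therefore validate the pipeline's correctness (segmentation alignment,
feature extraction, protocol wiring) and the *qualitative* orderings —
stage-aligned segmentation matches or beats blind windows on precision and
F-score while invoking roughly an order of magnitude fewer feature
extractions — not the absolute detection rates achievable on real data.

## Degenerate inputs and error handling

Non-finite samples, non-monotonic timestamps, missing CSV columns, unknown
unit modes, empty stages, fs mismatches, out-of-order streaming samples,
single-subject LOSO and single-class threshold fitting all raise typed
errors; a LOSO fold with single-class training data is skipped with a
warning rather than failing the run. Empty streams and quiescent streams
segment to the empty list. A posture window that extends past stream end is
evaluated on the available suffix (empty suffix → non-fall).

## Known limitations

* The FSM timer semantics at state-transition boundaries (expiry sample
  membership, carry-over arithmetic) admit more than one self-consistent
  reading; the choices above are fixed, documented, and pinned by
  hand-traced transcripts, but other implementations may differ by one
  sample at stage boundaries.
* Dataset loaders are dialect-configurable adapters (column map, unit mode,
  scale, per-dataset sampling rate); no specific corpus layout is
  hard-coded, and the sampling rate must always be supplied explicitly.
* Energy/cost accounting is a segment-count proxy; no hardware energy model
  is implemented.
* Single-accelerometer only: no gyroscope/barometer fusion, no multi-class
  fall typing, no adaptive thresholds.
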