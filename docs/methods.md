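# Methods

This note documents the models and measurement procedures `singrec`
implements, the defaults it ships with and why, what the simulators do
and do not emulate, and the numerical choices that matter for
reproducibility.

## Pitch representation

All pitch is carried as real-valued MIDI numbers under 12-tone equal
temperament, `midi = 69 + 12·log2(f0/440)`, so 100 cents is one
semitone. Rounding to integer MIDI — needed for interval sequences,
pitch-class profiles and "correct note" membership — uses
round-half-away-from-zero, which is symmetric for up/down deviations and
avoids banker's-rounding surprises at exact quarter-tone boundaries.
Unvoiced pitch-track frames (empty or non-positive f0) are retained as
missing and excluded from statistics; dropping them would silently bias
variance and autocorrelation estimates.

## Melodic similarity (opti3)

`opti3` combines interval, rhythm and harmony similarity with weights
3.027, 2.502 and 1.439. The raw weighted sum reaches 6.968 for identical
melodies; because the score is used as a [0, 1] outcome variable in the
downstream models, the default divides by the weight sum
(`normalize=True`), with the unnormalised sum available via a flag.

- **ngrukkon** compares count profiles of interval n-grams
  (`1 − Σ|f_a − f_b| / (N_a + N_b)`). The default n-gram length is 3;
  when a melody is too short, n falls back to the shorter melody's
  interval count so 2–3-note items remain scorable. Averaging over
  n = 3…8 is available (`average_ngram_lengths=True`) since either
  convention is defensible; the single-n default is documented here as
  the package's choice. Interval n-grams do not wrap octaves: a
  14-semitone leap is not a whole tone.
- **rhythfuzz** first "fuzzifies" durations into five classes by
  `log2(d / median d)` against boundaries ±0.5 and ±1.5, making the
  classes tempo-invariant, then applies the length-normalised edit
  distance `1 − d(a,b)/max(|a|,|b|)`.
- **harmcore** labels contiguous 2-second windows of each melody with
  the best-matching of the 24 Krumhansl–Schmuckler keys (duration-
  weighted pitch-class profile, Pearson correlation against the
  rotated 1990 probe-tone vectors) and edit-compares the label
  sequences. Fixed time windows are used for both rhythmic and
  arhythmic stimuli because arhythmic items have no bar structure; the
  window length is configurable. Key ties break deterministically:
  lowest tonic pitch class first, major before minor.

All components are symmetric, lie in [0, 1], and equal 1 for identical
melodies. ngrukkon and rhythfuzz are invariant to transposing either
melody; harmcore is invariant to transposing both together.

## Accuracy measures

Alignment between target and recall is positional (index by index up to
the shorter length); order-sensitive alignment is deliberately the
similarity module's job, keeping the two measure families independent.
Deviations are measured in cents rather than Hz, making them register-
free. Precision (the spread of productions of a repeated target pitch or
interval) is undefined — reported as missing, not zero — when nothing in
the aligned region repeats. "Correct note" membership uses absolute
rounded MIDI, since stimuli are transposed into the singer's range
before presentation; a pitch-class (octave-equivalent) flag exists but
is off by default.

## Long-note measures

Seven statistics summarise a sustained-note pitch track: mean absolute
cents deviation from the target (accuracy), voiced-f0 variance in Hz²,
DTW distance between the cents-deviation contour and an ideal flat
contour, mean sample autocorrelation over lags 1…L/2, a Wald–Wolfowitz
runs-test z about the median (median-equal frames dropped; NaN for a
constant track), and the count and second-onset time of mean
changepoints.

Numerical choices:

- **DTW** uses |a−b| local cost with steps (1,1), (1,0), (0,1); the
  optimal accumulated cost is divided by the warping-path length so the
  distance does not trivially grow with trial duration. Ties among
  predecessors go to the diagonal (shortest path). A numba-compiled
  kernel accelerates the DP when numba is available; semantics are
  identical without it.
- **Changepoints** use PELT with the residual-sum-of-squares mean-shift
  cost scaled by a robust difference-based MAD variance estimate and an
  MBIC-style penalty of 3·log(n) per changepoint (configurable),
  matching the defaults of the R `changepoint::cpt.mean` routine this
  measure family was defined around. A noiseless piecewise-constant
  series falls back to exact level-shift detection.
- **Smoothing.** A 5-frame running median (`smooth=True`) is provided to
  approximate a pYIN-style smoothed track when callers hold raw frame
  estimates. It is **off by default**: the package treats its input as
  the transcriber's final (already smoothed) track, and the measures
  then retain their textbook sampling behaviour — mean |deviation| of
  white noise equals σ√(2/π), and the runs-test z is N(0, 1) under an
  i.i.d. null, properties the test suite calibrates against. Applying
  the median filter would re-smooth and break both.

Missing fields are per-field, not per-call: a constant track yields a
NaN runs test but valid accuracy, and the second-changepoint time is NaN
whenever fewer than two changepoints are found. Trial averaging is
field-wise over non-missing values.

## Melodic features

- `i_entropy`: Shannon entropy (bits) of the interval distribution,
  intervals clamped to ±12 semitones (25 classes), normalised by
  log2(25).
- `d_entropy`: entropy of the five duration classes, normalised by
  log2(5); exactly 0 for isochronous (arhythmic) items.
- `tonalness`: the maximum of the 24 Krumhansl key correlations of the
  duration-weighted pitch-class profile. A single-pitch-class melody has
  no defined correlation and is signalled; a perfectly flat multi-class
  profile is scored 0 (no key preference).
- `step_cont_loc_var`: the melody rendered as a duration-weighted pitch
  step function over its span, sampled at 64 equidistant points (the
  FANTASTIC convention); the value is the mean absolute difference of
  adjacent samples, invariant to uniform tempo scaling.
- `log_freq`: natural log of the relative frequency of the item's
  interval sequence among equal-length corpus windows, with a 0.5
  pseudo-count for unseen items. The interval-sequence identity basis is
  transposition-invariant, matching the item bank's deduplication key.

## Item bank

Corpora are tokenized into every contiguous 3–15-note window (15 notes
as a practical upper bound on short-term memory span for unknown
melodies; both bounds configurable). Duplicates are removed on the
interval sequence — the transposition-robust choice, consistent with
range-based transposition at test time — with the duration-class
sequence added to the key for rhythmic banks. Ordering is deterministic
(corpus order, start, length) and rebuilding from the same corpus is
byte-identical.

Predicted item difficulty is a fixed-effects linear predictor, clipped
to [0, 1], under three published coefficient sets: arhythmic
(intercept 0.74; N −0.01, step-contour −0.32, tonalness +0.13,
log-freq +0.02), rhythmic (0.37; N −0.01, step-contour −0.50,
log-freq −0.02, duration entropy −0.26, interval entropy −0.19), and a
combined set with a rhythmic-indicator main effect (−0.15) and a
melody-type × duration-entropy interaction. Lower predicted score means
a harder item.

## Triage

SNR is `20·log10(RMS_signal / RMS_noise)` over the full recordings; the
default gate is 14 dB, below which pYIN-class transcribers degrade
substantially (a 0 dB profile is available for legacy-style screening).
A silent noise recording is an undefined-SNR error, distinct from a
failed gate. Vocal range is the rounded median MIDI of the voiced frames
of a sung low note and high note — the median survives scattered octave
errors — and stimuli are shifted by a whole number of semitones
(round-half-away-from-zero) so their mean pitch matches the range
centre; melodies already within half a semitone are left alone, which
also makes the operation idempotent.

## Explanatory IRT and composites

Trial outcomes on [0, 1] are fitted with a linear mixed model
(REML, statsmodels MixedLM): item features as fixed effects, participant
as random intercept. Three specifications mirror the published models
(combined / arhythmic / rhythmic); only first attempts enter by default.
Ability scores are the random-intercept BLUPs. Nakagawa's decomposition
uses the variance of the fixed-effect linear predictor:
R²m = σ²_f/(σ²_f+σ²_r+σ²_e), R²c = (σ²_f+σ²_r)/(σ²_f+σ²_r+σ²_e).

Composites are built by standardised PCA with varimax rotation;
variables with communality below threshold (0.75 for the long-note
pipeline, 0.30 for the accuracy pipeline) are dropped lowest-first with
refitting. Component scores use the regression method (Z R⁻¹ Λ), the
conventional choice where the extraction method is not otherwise
specified. Component signs are fixed deterministically (largest loading
positive). Note that varimax-rotated PCA loading columns are *not*
mutually orthogonal when eigenvalues differ; the rotation is orthogonal
and communalities are preserved, which is what the tests assert.
Retention uses Horn's parallel analysis: observed correlation
eigenvalues against the 95th percentile of eigenvalues from 100
standard-normal datasets of the same shape, stopping at the first rank
that fails.

## Simulators

`simulate_recall` perturbs a target note-by-note: Gaussian pitch error
in cents, log-normal duration jitter, independent deletions, and
insertions drawn uniformly near the melody's register.
`simulate_long_note` builds a 5-second, 100 frames/s track whose cents
deviation is `drift·t − scoop_depth·e^(−t/τ) + vibrato + white noise`;
the exponential term reproduces the under-pitched onset glide ("scoop")
that an early second changepoint detects. `simulate_study` drives whole
trial tables: abilities N(0, σ_a), outcome = clip(linear predictor +
ability, 0, 1) plus truncated-normal noise kept inside [0, 1] —
truncated-normal rather than beta noise because the downstream analysis
is a linear model and an extra link would confound recovery checks.
Every generator is a pure function of its parameters and seed.

What the simulators do **not** emulate: transcription artifacts (octave
jumps, spurious onsets, merged notes), systematic key-shifted recalls,
serial-position effects, vibrato–noise interactions, and any
participant-level correlation between pitch error and rhythm error.
Passing recovery tests therefore show the estimators are consistent
under the assumed error structure, not that real sung data meets that
structure.

## Problem sizes and determinism

The shipped test and acceptance runs use: 500 replicates for the
long-note noise calibration (5 s × 100 Hz tracks), 1000 replicates of
n = 500 for the runs-test null, 1000 random melody pairs for the
similarity property sweep, the full ≤6-length/3-symbol pair enumeration
(~1.2 M pairs) for the edit-distance oracle, 100 × 20 and 200 × 20
participant × item studies for coefficient and ability recovery, and
n = 300 × 6 indicators for the composite-structure recovery. Recovery
experiments draw item features independently (uniform over realistic
ranges, with the linear predictor kept inside the unit interval) because
corpus-derived features make item length and log frequency nearly
collinear, which would leave the length coefficient unidentified at
bank-sized item sets — a property of small designs, not of the
estimator. All stochastic tests are seeded; the acceptance script
derives every stream from its `--seed`.

## Known limitations

- No audio decoding or f0 estimation: the package starts from note
  tracks and pitch tracks produced by an external transcriber.
- The combined difficulty model's interaction terms require knowing the
  trial type; items scored with the wrong type get the wrong predictor.
- MixedLM occasionally warns that the random-intercept variance sits on
  the boundary for near-zero ability variance; the fit is still
  reported, as masking singular fits would hide a real data property.
- MIDI ingestion reads one monophonic track (first with notes) from
  format 0/1 files and truncates overlaps at the next onset; polyphonic
  corpora are out of scope.
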