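# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind `speechdep`, and what the synthetic-corpus experiments
do and do not establish.

## Problem setting and labels

One recording per speaker; the target is the binary depression label
derived from the PHQ-8 questionnaire score (0–24): label 1 iff score ≥ 10.
`binarize_phq8` enforces the range and the threshold; rosters reject
duplicate speaker ids.  Diarization is out of scope: the corpus reader
consumes either pre-cleaned audio or a segment CSV (participant vs
interviewer spans) and concatenates participant spans in time order.  When
neither is available, an optional fallback removes silences by frame
energy: 25 ms frames, dropping frames whose RMS falls below 0.5 % of the
recording's peak frame RMS.  All audio is polyphase-resampled to 16 kHz
mono; multichannel input is averaged to mono.

## Balanced crop sampling

Samples are non-overlapping 4-s crops aligned to multiples of 4 s from the
recording start; alignment and non-overlap prevent near-duplicate samples
from leaking between them.  A speaker of duration d supplies
floor(d / 4) crops.  The training selection maximizes 2·k·c over candidate
crops-per-speaker values c (the distinct counts), where
k(c) = min over classes of the number of speakers with ≥ c crops; ties in
the total break toward smaller c, which retains more speakers and reduces
per-speaker bias.  When a class has more than k eligible speakers, k are
drawn uniformly without replacement; each selected speaker's c offsets are
drawn uniformly without replacement from its aligned offsets.  Both draws
are seeded and the seed is recorded — an unseeded plan is refused.
Evaluation-split speakers are never dropped: each contributes
min(cap, available) crops (cap defaults to 89).

## Features

Log-spectrogram of each crop: STFT every 32 ms (hop 512 samples) over
64 ms (1024-sample) Hamming windows, 1024 FFT points, entries
log(|STFT| + ε) with ε = 1e-10 (below any voiced magnitude; keeps silence
finite).  Frame-count convention: T0 = floor(n_samples / hop), realized as
centered framing (half-window zero padding) with the trailing boundary
frame dropped; a 64 000-sample crop therefore gives exactly 513 × 125.
Plain non-centered framing would give 124 frames and fully centered 126;
the adopted convention reproduces the canonical printed geometry
deterministically and is documented here rather than configurable per call.
Each spectrogram is min-max normalized to [0, 1] independently; a constant
matrix maps to zeros.  Per-spectrogram normalization makes the model
invariant to waveform gain (log turns gain into an additive constant that
min-max removes); corpus-level standardization is deliberately not
implemented.

## Classifier

Layers: (1) convolution with N filters of size F0 × 1, stride 1 along
time, ReLU — because each filter spans the whole frequency axis, the layer
is a dense linear map applied per time frame, and the implementation is
plain (BLAS-backed) NumPy linear algebra with explicit backpropagation;
(2) temporal max-pool, kernel (1, k), stride (1, s), padding p; (3) flatten
of width n3 = T1·N; (4) dense n4, ReLU; (5) dense 1, sigmoid.  Trainable
parameters: N(F0+1) + (T1·N)·n4 + n4 + (n4+1).

Pooling convention: the padding "preserves the extremes" and p = s in the
canonical setup, which is read as same-padding, T1 = ceil(T0 / s) — 32 for
the canonical geometry.  The explicit textbook formula
floor((T0 + 2p − k)/s) + 1 (= 33) is implemented behind
`pool_mode="explicit"`; the same-padding convention is the default.

Training: binary cross-entropy, batch 80, Adadelta (ρ = 0.95, eps = 1e-6)
scaled by a per-epoch learning-rate multiplier decaying exponentially
lr(e) = lr_start·(lr_end/lr_start)^(e/(E−1)) from 1 to 0.01 — only the
endpoints of the schedule are prescribed; the exponential shape is this
package's choice.  Weights are Glorot-uniform from a seeded generator; no
dropout or batch normalization (none are part of the architecture).
Sample labels inherit the speaker label.  A fixed seed reproduces final
weights bit-for-bit on a single-threaded run; a non-finite loss raises a
divergence error carrying the epoch index.

## Aggregation, ensembling, ties

Sample probabilities become speaker decisions by either the mode of the
thresholded sample labels or the thresholded mean probability; all
threshold comparisons use ≥ 0.5, so the boundary maps to depressed (a
fixed convention, required because the boundary case is otherwise
unspecified).  The ensemble trains M machines on identical data with
distinct seeds and fuses by one of three orderings (probability averaging;
pooled sample-label mode; mode of per-machine speaker modes).  Method 1 is
algebraically the grand mean of all M·L_i probabilities — an identity the
tests verify on random tables.  Mode ties fall to a fair coin seeded by
(tie seed, speaker id[, machine]), reproducible yet independent across
speakers.  The default operating point is Method 1 with M = 50; the
F1-vs-M analysis draws machine subsets without replacement within a draw
and with replacement across draws (near the pool maximum the number of
distinct subsets is small, so draws necessarily repeat).

## Evaluation

Per-class precision, recall and F1 (harmonic mean) with that class as
positive, plus shared accuracy, via scikit-learn.  A class with no
predicted positives gets precision 0 with a warning, keeping degenerate
runs comparable.  Cross-validation is stratified and speaker-disjoint; the
"concatenate partial results" reading is adopted by default (each test
speaker counted once per fold in the pooled prediction list), with a
per-fold-average alternative behind `pooling="per_fold"`.  Relative
improvement is 100·(F1_new − F1_ref)/F1_ref, computed from F1 values at
their printed precision when comparing against published tables.

## Synthetic corpus

Each speaker is a harmonic complex (fundamental 120 Hz, ten harmonics with
1/h amplitudes) whose pitch wanders under a slow (≈ 4 Hz control-point)
unit-variance random modulation of depth 0.08, plus low-band (< 1 kHz,
gain 0.30) and high-band (2–7 kHz, gain 0.35) shaped noise, peak-normalized.
For the depressed class, modulation depth and high-band gain are both
scaled by (1 − 0.8·effect): the class signal lives in slow temporal
modulation and spectral tilt, which survive per-spectrogram min-max
normalization, rather than in level, which would not.  Durations follow a
truncated normal (≥ 4 s) defaulting to mean 547.29 s, sd 237.58 s, and the
default roster is 100 non-depressed vs 42 depressed speakers — the
statistics of the clinical corpus being emulated.  PHQ-8 scores are drawn
uniformly within the label-consistent range (0–9 / 10–24).  Per-speaker
randomness derives from seed sequences keyed [seed, label, index], so a
corpus is append-only under roster growth.

What this establishes: the pipeline recovers a class signal of the stated
kind, the ensemble's variance shrinks and its mean F1 does not degrade as
machines are added, and with no signal the system performs at chance.
What it does not establish: performance on real clinical speech, whose
depression markers are subtler, multi-factorial and entangled with channel
and speaker covariates far beyond a two-parameter signature.

## Problem sizes used in tests

The end-to-end suites run scaled-down study conditions chosen once:
28 speakers per class (20 train / 8 test), duration law (48 s, 12 s), a
pool of 16 machines at 12 epochs for the separable-corpus experiments;
16 speakers per class (10 train / 6 test), (32 s, 8 s), 3 machines at
8 epochs for the null-corpus experiment; 50 subset draws for the F1-vs-M
comparison.  Epoch budgets below the canonical 50 are sufficient because
the synthetic signature is far stronger than clinical reality; all other
hyperparameters stay at their canonical values.

## Known limitations

- The STFT centering convention is a documented package choice; other
  tools' spectrograms will differ near crop boundaries.
- Adadelta is re-implemented; its accumulator constants (ρ = 0.95,
  eps = 1e-6) follow the optimizer's original formulation and are not
  exposed as configuration.
- The exclusion list for low-quality recordings is an interface
  (`load_roster(..., exclude=...)`), not a reproduction of any particular
  corpus's removals.
- `crossval_evaluate` leaves the held-out fold unused (no early stopping),
  matching a fixed-epoch training regime.
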