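# Methods

`actiseg` detects and recognises sport motion states in 6-channel
wrist-IMU recordings (triaxial acceleration + triaxial angular
velocity, 50 Hz).  It implements two complementary procedures: an
anchor-based temporal interval detector with shared-convolution
recognition for *non-periodic* activities with complex motion states,
and a classification-guided periodic matcher for *weakly periodic*
activities.  Because no suitable annotated datasets are openly
available for either setting, the package ships a first-class
synthetic-data generator that reproduces the statistical structure the
methods rely on; all quantitative results the test suite and
`scripts/acceptance.py` report are measured on that synthetic data.

## Preprocessing and the virtual image

Each channel is independently standardised to zero mean and unit
variance per recording (a constant channel maps to zeros), then
smoothed with a Gaussian kernel (σ = 1 sample by default, truncated at
±4σ, reflective boundary).  Per-recording z-scoring is scale-free and
standard for consumer IMUs whose accelerometer and gyroscope ranges
differ by orders of magnitude; its known limitation is discussed under
*Limitations*.

For the convolutional encoder the six channels are stacked into an
8-row *virtual image*: rows 0–2 acceleration, rows 3–4 identically
zero, rows 5–7 angular velocity.  The zero rows stop 2-D kernels from
mixing the two sensor modalities across the seam.  The time axis is
zero-padded on the right to a multiple of 4 — the encoder's horizontal
stride — so every input length is admissible:
`N_pad = ceil(T/4)·4 − T`.

All coordinates in the package are 0-based, half-open `[start, end)`
sample intervals.

## Anchor-based interval detection

At each of the `T/4` encoder feature positions, ten candidate
intervals ("anchors") are preset, centred on the position's receptive
field centre (sample `4i + 2`), with lengths
16, 24, 32, 40, 48, 56, 64, 72, 80, 96 samples (0.32–1.92 s).  This
grid covers every interval of length 16–96 at every position with
intersection-over-union (IOU) above 0.5; the worst case over a
400-sample signal is 0.78 (checked exhaustively in the tests).

An anchor is *foreground* during training when its IOU with some
ground-truth interval exceeds 0.5; it regresses two offsets against
its best-matching ground truth:

    α = (g_s + g_e − a_s − a_e) / w        (centre shift ÷ anchor width)
    β = log((g_e − g_s) / w),              w = a_e − a_s

and decoding applies `centre += α·w/2`, `width ·= exp(β)` — the exact
algebraic inverse, so zero offsets return the anchor and
decode∘encode is the identity to 1e-9 (tested on 1000 random pairs).
Decoded intervals are clipped to the unpadded signal extent.

The loss is `L1 = Lscore + Loffset`: softmax cross-entropy of the
foreground/background scores averaged over *all* anchors, plus
smooth-L1 (0.5x² inside |x|<1, |x|−0.5 outside) offset error averaged
over foreground anchors.  No foreground/background re-balancing is
applied by default (an optional `balance_sampling` flag subsamples
background 3:1); on the synthetic conditions the plain average trains
fine with Adam.

Inference keeps anchors with `p_fg > p_bg`, decodes them, applies
greedy non-maximum suppression at IOU 0.3 and optionally truncates to
the top-N by foreground score (N = 5 for the proposal-recall
protocol; all post-NMS candidates feed recognition).

### Encoder and heads

No deep-learning framework is used: the networks are implemented
directly on numpy with explicit backpropagation (`actiseg._nn`),
gradient-checked numerically in the tests.  The encoder is four
convolutions with horizontal-only kernels and pooling-free strides —
(8×7) stride 2 collapsing the image height, then (1×5) stride 2,
(1×3), (1×3), all ReLU, 32 output channels — giving total stride 4
and a 31-sample receptive field.  Outputs at one feature position
depend only on samples inside that receptive field (tested by
perturbing the signal outside it).  Two 1×1-convolution heads (linear
maps per position) emit 2 scores and 2 offsets per anchor scale.

### Shared-convolution recognition

Candidates are classified without re-convolving their samples: a
candidate `[s, e)` is projected onto the feature map by
`s_f = floor(s·lf/los)`, `e_f = ceil(e·lf/los)`.  Floor/ceil (rather
than symmetric rounding of both ends) makes the projected span always
cover the candidate, never degenerate, and monotone under interval
inclusion — symmetric rounding violates all three for short
candidates.  The feature slice is adaptively average-pooled into
`ls = 8` bins (contiguous, as equal as possible; width-1 nearest bins
when the slice is shorter than 8), flattened (8×32 values) and passed
through a fully connected softmax head over C+1 classes — the C
motion states plus **None** for candidates matching no ground truth
(IOU ≤ 0.5, the same threshold as the detector).

Training is two-stage.  Stage 1 trains the detector alone until the
loss is stable.  Stage 2 minimises `L1 + L2` jointly (`L2` = mean
cross-entropy over candidates), with both gradients flowing into the
shared encoder.  The recognition head is fed the union of the
detector's current post-NMS candidates (capped at 8) and the ground
truth jittered by up to ±4 samples per boundary, so it always sees
high-quality intervals even while the detector is immature.  Final
detections drop None-labelled candidates; the reported confidence is
`p_fg · p_class` (the paper-style pipeline emits the two scores
separately; the product is this package's ranking choice for AP).

## Classification-guided periodic matching

For weakly periodic signals the matcher extracts one movement cycle at
a time.  At position `j` it computes, per channel,

    R[i][t] = Σ_{n=0}^{N−1} S[i][j+n] · S[i][j+n+t],   t = 0…N−1,

requiring samples through `j + 2N − 1` (a `zero_pad` option
zero-extends past the record end instead).  `N` defaults to 3× the
maximum configured period ("2–3× the maximum cycle"); the step gap `z`
defaults to the minimum configured period.  Each channel's *first
peak* is the smallest lag ≥ `z/2` that rises strictly, falls
non-strictly, and exceeds half the window's self inner product
`R[i][0]`.  The minimum lag excludes the lag-0 neighbourhood where R
is maximal for smooth signals; plateau peaks take their first index.
Channels then vote: the largest cluster of first-peak lags pairwise
within 10 samples wins (ties to the smaller mean); with ≥ 2 votes the
cluster mean is the consensus period.

The scan loop: no consensus → advance by `z`; consensus → re-match
once at `p − z/2` (floored at the previous segment's end) to align
the cycle start, extract one period, and ask the classifier.  A
recognised motion state records the segment and continues from its
end; None advances by `z`.  The position strictly increases every
iteration, so the loop terminates on any finite input.

**Tail completion.**  Autocorrelation can never confirm the last
cycles of a block — fewer than two periods of signal remain ahead of
them.  Once the (shrinking) window can no longer reveal the running
period, the matcher continues segmenting the tail with the last
confirmed period, still gated by the classifier, accepting one final
segment down to 0.75 of that period (boundary drift leaves the last
true cycle slightly short).  Without this, every block would
undercount by 1–2 cycles and exact count conservation would be
impossible in principle.

On zero-jitter noiseless blocks the recovered count equals the
simulated count exactly and boundaries agree within ±3 samples; with
period jitter of sd 3 samples the consensus period tracks the true
mean period with MAE ≈ 0.3 samples over 50 blocks (both recomputed by
the test suite and acceptance script).

## Segment classifiers

All classifiers share one contract: `fit(segments, labels)`,
`predict_one(6×L) → label`, `predict_proba_one → distribution over
C+1` (None last).

* **CNN** — input resampled per channel by linear interpolation to
  6×128 (≈ 2.56 s); three strided convolution blocks each followed by
  an additive-shortcut residual pair; global average pooling; softmax
  head.  The head is zero-initialised so the starting loss is exactly
  log(C+1).  Trained with Adam on the mean cross-entropy.
* **Classical (knn / nb / rf / svm)** — a 41-value handcrafted vector:
  per channel the mean, energy (Σx²), variance, interquartile range,
  and the summed level-1/level-2 detail coefficients of a db4 discrete
  wavelet transform; plus Pearson correlations of the five adjacent
  channel pairs (0 for zero-variance pairs).  Features are
  standardised; the SVM uses an RBF kernel with C ∈ {0.1,1,10,100} and
  γ ∈ {0.01,0.1,1} grid-searched under stratified 3-fold CV; knn
  defaults to 1 neighbour; rf uses 200 trees.

**None-class material** is harvested from the generators: windows
straddling a cycle boundary, aligned-but-partial cycles (0.5–0.8 of a
period), and for the non-periodic setting background spans and
windows with IOU ≤ 0.3 against every burst.  The paper-style pipeline
needs a None class but leaves its provenance open; this choice teaches
the gate precisely the failure modes the matcher can produce.

## Sliding-window baselines

Two conventional detectors for comparison: **ASSW** (a set of sliding
windows, lengths 30/40/50 samples, overlap 0.4, one
specially-trained classifier per length, windows labelled by IOU > 0.5)
and **FLSW** (fixed length 60, overlap 0.4, a window labelled by the
ground-truth interval it fully contains).  Both classify every window
with handcrafted features + SVM, keep non-None windows scored by class
probability, and merge with NMS at 0.3.  They are evaluated with the
same mAP as the interval method.  During baseline training, None
windows are subsampled to ≤ 2× the positive count to keep the SVM
tractable; this is a training-set-size control, not part of the
evaluated protocol.

## Evaluation

A detection matches a ground truth when labels agree and IOU > 0.5;
matching is greedy in descending score with each ground truth
claimable once (PASCAL-VOC convention — the printed definitions of
TP/FP/FN leave the assignment procedure open).  Precision
`TP/(TP+FP)`, recall `TP/(TP+FN)`; AP is the all-point integral of
the interpolated precision envelope over recall (matching the
integral form ∫P(R)dR rather than 11-point sampling); mAP averages
classes with ≥ 1 ground truth.  Top-5 proposal recall is
label-agnostic, as the detector scores only foreground.  Cycle
counting is scored by per-class absolute count error plus per-cycle
label accuracy under maximum-overlap matching of segments to true
cycles.

## Synthetic data: what it does and does not emulate

**Non-periodic records** (badminton-like): 10-s, 50-Hz records of
Gaussian background (sd 0.3) with 2–4 non-overlapping bursts (≥ 8
samples apart).  Bursts are Hann-windowed sums of 2–3 sinusoids;
"serve" is 3–5 Hz, acceleration-dominant, 24–56 samples; "swing" is
6–10 Hz, gyro-dominant, 32–80 samples; per-channel amplitudes
randomise ±50% around unit scale.  Twelve synthetic subjects are
assigned round-robin and all splits are subject-wise (four folds of
three subjects).

**Weakly periodic records** (swimming-like): concatenated blocks of
four strokes, each block repeating its cycle waveform with per-cycle
period `base + N(0, 2)` samples; blocks are shuffled per record and
cross-faded over ≤ 4 samples; additive noise sd 0.1.  The stroke
waveform design encodes three deliberate properties:

1. *Shared gross kinematics*: all strokes share the dominant
   first-harmonic amplitude and channel-phase profile, differing in
   their weaker (0.1–0.45 amplitude) second and third harmonics — as
   strokes of one swimmer share the arm-cycle and differ in finer
   detail.
2. *Overlapping periods*: base periods 65, 72, 80, 88 samples
   (1.3–1.8 s), since stroke-duration distributions overlap in
   practice; period alone cannot identify the stroke.
3. *Intra-cycle non-stationarity*: an activity envelope
   `g + (1−g)·(½(1−cos φ))^q` (floor g = 0.25, power q per stroke in
   1–3) gives each cycle an active "pull" and a quiet "glide".

Properties 1–3 jointly reproduce the premise of the weakly periodic
setting: a fixed-length window cuts cycles at arbitrary phase and
straddles stroke changes, so its content is genuinely ambiguous, while
a correctly segmented single cycle is not.  Early pilot versions with
spectrally disjoint, stationary templates made the fixed-window
baseline as accurate as cycle-aligned classification, which
contradicts that premise; the defaults above were then fixed and all
reported comparisons use them unchanged.

The generators do **not** emulate gravity/orientation effects, sensor
bias or saturation, inter-subject kinematic variation beyond random
amplitudes, fatigue drift, or non-target movements (turns, rests).
Passing results therefore demonstrate correctness and the expected
qualitative orderings of the algorithms, not field performance on real
recordings.

## Problem sizes and numerical choices

The shipped study designs (`actiseg.benchmarks`) use 260 ten-second
non-periodic records (one subject fold held out, ≈ 195 training
records) with 25 detector epochs + 12 joint epochs, and 12 training /
6 test weakly periodic records with 6 cycles per stroke block — sizes
at which the complete suite trains in a few minutes on one CPU core
while leaving the measured quantities stable.  Adam uses lr 2e-3
(detector/joint) and 1e-3 (cycle CNN); training order is shuffled by
the seeded generator, and every stochastic component (simulation,
initialisation, shuffling, subsampling) derives from one integer seed,
so identical seeds give bit-identical models and metrics.

Degenerate inputs are handled explicitly: constant channels normalise
to zero; zero-variance correlation pairs report 0; candidate
projections never collapse below one feature; consensus periods round
half-up to integer sample extents; ties in anchor–ground-truth
matching go to the earliest ground truth, in peak plateaus to the
first index, and in vote clusters to the smaller mean lag.

## Limitations

* Per-recording z-scoring normalises a *burst-free* recording's
  background to unit variance — louder than the background of
  burst-containing recordings — so a well-trained detector can emit
  spurious low-confidence candidates on pure noise.  The pipeline's
  confidence on such input stays well below its confidence on real
  bursts (tested), but rejection is not absolute; deployed systems
  would calibrate the scale on device instead.
* The interval detector assumes motion states of 16–96 samples; longer
  states need a wider anchor ladder.
* The periodic matcher assumes one motion state at a time and locally
  stable periods; simultaneous mixed movements and abrupt tempo jumps
  inside a block are out of scope.
* All accuracy figures are synthetic-data measurements; see above.
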