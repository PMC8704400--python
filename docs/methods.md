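# Methods

`trampohar` re-implements a complete recognition pipeline for trampoline
motions measured by a wrist-worn accelerometer: fixed-window segmentation, a
hand-crafted-feature + Random-Forest baseline, a family of 1D convolutional
networks whose flagship uses global average pooling (GAP) instead of a
fully-connected head, leave-one-subject-out evaluation, label merging, and
four per-user adaptation schemes.  This note records the model assumptions,
the conventions frozen where the published protocol leaves latitude, and what
the synthetic cohort does and does not establish.

## Signal model and windowing

The input is a 3-axis acceleration stream in G (1 G = 9.8 m/s², the unit
convention of watch motion frameworks), nominally sampled at 100 Hz.  One
*recording* is a single labeled bout of one motion — six classes in a fixed
order: stand (ST), walk (WL), march (MR), two-leg jump (TJ), and one-leg
jumps left/right (LJ, RJ).  Recordings are cut into non-overlapping windows
of 64 samples (0.64 s) with stride 64; an incomplete trailing window is
dropped rather than padded, and windows never span recordings, so a window
always carries a single label.  Windowing is index-based: timestamps are
validated (strictly increasing) but not used to place windows, since the
sampling is nominally uniform.

For the CNNs each 64×3 window is laid out axis-major (all x, then y, then z)
as a 192-sample single-channel sequence.  This is the layout under which the
flagship architecture's printed intermediate sequence lengths (192 → 96 → 48
→ 24 → 12 → 6) are reproduced exactly; a 64×3 three-channel layout remains
available through `ModelSpec.input_shape` for comparison.

## Hand-crafted features (175)

Per window: 16 time-domain statistics per axis (moments, extrema, quartiles,
RMS, endpoints, zero-crossing rate), 3+3 inter-axis correlations (raw and
absolute), one frame-level intensity (mean Euclidean norm), and 9 spectral
statistics per axis per band plus 3 in-band inter-axis correlations for four
bands — all (DC-free up to Nyquist), low [0, 4.2), mid [4.2, 8.4) and high
[8.4, 12.6) Hz.  Conventions the published table does not pin down are frozen
as follows (and enforced by tests):

* population moments; kurtosis is excess; both imputed 0 when the variance is
  below 1e-12, so constant windows are well-defined;
* zero-crossing rate counts strict sign changes of the *mean-removed* signal
  over (N−1) sample pairs — without mean removal the ~1 G gravity offset
  would zero the count on every realistic window;
* quartiles by linear interpolation; spectral quartiles are quartiles of the
  in-band magnitude values;
* the spectral "2nd maximum" is the largest bin at least two bins away from
  the argmax (adjacent bins mostly carry leakage of the same peak); when a
  band has no such bin, value and frequency are reported as 0;
* correlations with a zero-variance argument are 0; band edges are
  closed-left/open-right, so bands are disjoint; intensity is frame-level,
  not per-axis.

At 100 Hz and window 64 the bin spacing is 1.5625 Hz, so the low band holds
bins {1, 2}, mid {3, 4, 5}, high {6, 7}, and "all" bins 1–32.  Every feature
is checked against a straight-from-definition oracle (direct-summation DFT,
loop-based moment formulas) to 1e-9 relative on random windows.

## Architectures

The flagship network ("ours") is a VGG16-style 1D CNN: conv blocks with
filter counts 16,16 | 32,32 | 64,64,64 | 128,128,128 | 128,128,128 (13 conv
layers), a size-2/stride-2 max pool after each block, then GAP and a
softmax(6) layer.  Only the layer kinds, filter counts and output shapes of
this stack are published; the remaining choices follow the VGG16 lineage and
are frozen here: kernel size 3 with same-padding, ReLU hidden activations,
Glorot-uniform initialization, pool rows interpreted as pool size 2.  The
GAP head makes the classifier parameters exactly 128·6+6; the model totals
308,310 parameters (≈1.2 MB at float32).

Baselines:

* **VGG16-FC** — identical extractor, head = flatten → two dense-128 layers →
  softmax.  The original fully-connected width (4096) is scaled to 128 to fit
  the 128-channel extractor; the published comparison only requires that the
  FC head strictly increase the parameter count, which holds (423,254).
* **Simple CNN** — a three-conv reference model whose exact internals are not
  published; reconstructed here as conv 32/64/128 (kernel 3), one pool, a
  dense-128 head without GAP (1.6 M parameters).  All comparisons against it
  are reconstruction-dependent.
* **Depth family** — `depth:k` for k = 1..19: conv layers in groups of three,
  16 channels doubling every completed group, a pool after each completed
  group (none after a trailing partial group), GAP + softmax head.

Training follows the published protocol: Adam (lr 1e-3), categorical
cross-entropy, minibatch 20, 100 epochs by default, no normalization,
augmentation, early stopping or validation split; raw G values enter the
network.  The network engine is written in numpy (same-padding im2col
convolutions, argmax-tracked pooling, analytic backprop) and is bitwise
deterministic given a seed, which turns "same seed, same weights" from an
aspiration into an exact contract.  The Random-Forest baseline uses
scikit-learn with 300 trees (no hyperparameters are published; the value is
logged and fixed).  Softmax ties resolve to the lowest class index.

## Evaluation

Leave-one-subject-out cross-validation: one fold per subject, the held-out
subject's windows never enter training, per-fold seeds derived from the run
seed.  Confusion matrices are rows = predicted, columns = correct; precision
is the diagonal over the row sum, recall over the column sum, F their
harmonic mean, and the headline accuracy is the *unweighted mean over
subjects* (pooled accuracy is reported alongside, since they differ when
subjects contribute unequal window counts).  Printed-style tables round
half-up to one decimal; full precision is kept internally.  Label merging
sums rows/columns over groups that must partition the six classes; totals
are conserved and within-group confusions move onto the diagonal, so pooled
accuracy cannot decrease.

Personalization assumes three of a user's five sets are available for
adaptation: `None` (base model untouched), `FT` (all weights fine-tuned),
`FT-Classifier` (softmax layer only; the extractor is verified bitwise
unchanged), `Mixin` (fresh training on the other subjects plus the user's
adaptation sets).  The published protocol does not say which sets test;
default: the first three sets (by index) adapt, the remaining two evaluate,
and `rotate_sets` averages over all ten 3-of-5 choices.  Fine-tuning epochs
are not published; default 20 (a small adaptation set needs fewer passes),
while `Mixin` uses the full configuration.

## Synthetic cohort

The study's human recordings are available only on request, so the package
ships a generator that emulates the collection protocol: 8 subjects × 5 sets
× 6 motions in protocol order, 10 s bouts at 100 Hz by default.  Each
subject draws a bounce cadence (1.2–2.6 Hz), amplitude scale, arm-swing
gain, asymmetry gain and noise level from a per-subject seed.  Classes are
built from a harmonic bounce carrier with cadence jitter: ST is noise about
a unit-norm gravity vector; WL is a lower-frequency (0.7× cadence),
low-amplitude quasi-periodic sway; MR alternates legs every cycle, which
puts sub-harmonic (half-cadence) energy into the envelope and the lateral
axis; TJ has the largest vertical amplitude; LJ/RJ share one construction
with a one-sided lateral lean and differ only by the sign of the lateral
channel, making them exact mirror images at equal seeds and deliberately the
most confusable pair.  All randomness flows through spawned seeds; cohort
generation is byte-reproducible.

What the generator guarantees (and tests enforce): intensity ordering
ST < WL < TJ on cohort average; more lateral half-cadence energy in MR than
TJ windows; LJ/RJ mirror symmetry; determinism.  What it does not attempt:
biomechanical fidelity, trampoline membrane dynamics, sensor drift, or the
real inter-subject variance (published per-subject accuracies spanning
67–88% suggest heterogeneity larger than the generator's default knobs).
Consequently the learning-stage checks are *property-based* — well above
chance under LOSO, scheme contracts, orderings — and synthetic accuracies
(typically >90%) must not be read as predictions of accuracy on human data.

## Problem sizes for the shipped checks

The acceptance script and the heavy tests run the full 8-subject, 5-set
cohort but with 5 s bouts (6 windows per bout, 1,440 windows) and 15
training epochs instead of 10 s/100 epochs — sizes chosen once so a complete
run (13-conv CNN LOSO, RF LOSO, and all four personalization schemes for all
eight subjects) executes on a single CPU core in minutes.  The loss curves
plateau well before 15 epochs on the synthetic task, and results at 10 s/100
epochs are qualitatively identical (higher absolute accuracy, same
orderings).

## Known limitations

* The numpy engine supports exactly the published architecture family
  (stride-1 same-padded convs, non-overlapping pools); it is not a general
  deep-learning substrate.
* Scheme comparisons near the synthetic task's accuracy ceiling compress the
  FT/Mixin gains that the published study observed on harder human data.
* The on-device half of the original system (model conversion, watch app,
  latency/battery measurements) is out of scope.
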