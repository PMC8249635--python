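# Methods

This note documents the model, the numerical choices, and the limits of
what the synthetic experiments demonstrate.

## From image to signal

A color image is converted to grayscale with ITU-R BT.601 luma weights
(0.2989, 0.5870, 0.1140) — the de-facto standard of image toolboxes; the
weights sum to 0.9999, so a constant image loses at most 0.0255 of 255
intensity units. Intensities stay real-valued after conversion (no
8-bit re-quantization) so no precision is lost before feature extraction.
Resizing, when requested, is bilinear with a Gaussian anti-aliasing
prefilter on downsizing.

Vectorization stacks columns top-to-bottom, left-to-right (column-major
flatten). It is exactly invertible given the image shape, and the multiset
of signal values equals the multiset of pixels. The signal carries a
*nominal* sampling frequency, fs = 300 Hz by default: images have no
physical time axis, so fs only fixes the scale on which frequencies are
reported. All frequency-domain features are invariant to multiplying the
signal by a constant gain.

## Time-frequency features

The spectrogram uses a Hamming window of 128 samples, hop 64 (50 %
overlap), FFT length equal to the window, one-sided power. These are
package defaults, chosen so the images this pipeline targets (150 × 150 to
250 × 250 px, i.e. signals of 22 500–62 500 samples) yield sequences of a
few hundred frames — a tractable recurrent-network input; all three are
configurable. The frame count is `floor((len − window)/hop) + 1`.

The global signal mean is subtracted before the transform. Image signals
sit on a large positive intensity offset; the resulting DC spike carries no
oscillatory information but would dominate the power-weighted mean
frequency (a 64 × 64 grating of period 6 px would report IF ≈ 12 Hz instead
of the designed 50 Hz). Removing the *global* mean (rather than detrending
each frame) leaves the DC bin statistically populated for broadband
signals, so the spectral entropy of white noise keeps its nominal
expectation.

Instantaneous frequency is the first spectral moment per frame, evaluated
on the spectrogram's bin grid; no phase-based estimator is used. Spectral
entropy is the Shannon entropy of the per-frame normalized spectrum,
divided by log₂ F by default so a flat spectrum scores 1 (a flag disables
the scaling). Frames with total power below machine-epsilon × max(peak
power, 1) are floored before normalization, which deterministically sends
degenerate frames to the uniform limit: IF = fs/4, scaled SE = 1. The
convention 0·log₂ 0 = 0 applies throughout.

A caveat on the white-noise calibration: for a single periodogram per
frame, the expected scaled SE of white noise is not 1 but
≈ (log₂ F − (1−γ)/ln 2)/log₂ F ≈ 0.90 at F = 65 (the entropy of a
Dirichlet(1,…,1) spectrum, slightly reduced by Hamming-window bin
correlation). Tests asserting SE ≥ 0.9 for white noise therefore sit at
the estimator's expectation and are seed-sensitive by ±0.002 at 63 frames.

## Time-space features

Each signal segment is delay-embedded with dimension 1 and delay 1 (the
states are the samples themselves), then partitioned by fuzzy c-means with
c = 3 clusters and fuzzifier w = 2 — the canonical setting. The FCM
implementation uses alternating optimization with convergence declared when
the largest membership change drops below 1e-5 (at most 100 iterations).
Centroids are initialized on the value-range quantiles of the segment, so
the result is deterministic without any random restarts; coincident initial
centroids are nudged apart by 1e-9. A point exactly on a centroid receives
crisp membership there (split equally if on several).

The fuzzy recurrence plot applies a *single* max–min composition,
`R(i,j) = max_q min(u_iq, u_jq)`, then forces the diagonal to 1 (the
composition alone can give `max_q min(u_iq, u_iq) < 1`). Symmetry holds by
construction. Iterating the composition to its transitive closure is
available as an opt-in (`transitive_closure`), not the default.

FRIE quantizes memberships to L = 256 gray levels via `round(μ·(L−1))` —
the 8-bit convention of FRP images; L is configurable. FRE sums the binary
entropy of all N² entries. Degenerate segments with fewer distinct values
than c are treated as fully recurrent (all-ones FRP, both entropies 0):
the limit of identical points is full recurrence.

Segmentation produces exactly T contiguous segments, T being the
spectrogram frame count, with the first `len mod T` segments one sample
longer; segments must be at least 8 samples. FCM is run independently per
segment (clusters are not shared across segments). Note that FCM
memberships are invariant to rescaling a segment, so the FRP entropies
respond to the *correlation structure* of a segment, not to its variance.

## Classifier and class modeling

The network is a bidirectional LSTM: 100 hidden units per direction
(sigmoid gates, tanh cell), reading the standardized T × 4 sequence forward
and backward; the two final hidden states are concatenated (200 features)
into a dense layer with one output per class and a softmax. Training
minimizes cross-entropy with Adam (β₁ = 0.9, β₂ = 0.999, lr 0.01), an L2
penalty of 1e-4 on the weight matrices (not biases), and global-norm
gradient clipping at 1. Minibatches are min(150, n) sequences, reshuffled
every epoch; default epoch budgets are 80 for two-class and 180 for
eight-class problems. Weights start Glorot-uniform with forget-gate biases
at 1. An optional convergence stop halts training when the epoch-mean loss
falls below a threshold (disabled by default). Everything — initialization
and shuffling — derives from one seeded generator, so a fixed seed gives a
bitwise-identical loss history. The forward/backward passes are plain
NumPy; gradients are verified against central finite differences in the
test suite.

Per-channel standardization (mean, sd pooled over all time steps of the
training sequences; sd floored at 1e-8) is fitted on training data only and
stored with the model.

Class modeling builds the training set for a designated target class: all
target-class training samples, plus one donor per other class replicated to
the target-class count (both the donor index and the replication count are
configurable; the default donor is the first sample of that class under a
seeded shuffle). The balanced set lets the network learn one class against
repeated counter-examples and neutralizes class imbalance by construction.
For more than two classes, either a single multiclass network is trained on
the target class's class-modeling set, or a one-vs-rest ensemble (one model
per class, argmax of each model's target-class score) — both modes are
provided.

Sequences of unequal length are handled by grouping a minibatch by length
and averaging gradients across groups; with the fixed pipeline all
sequences share T, so there is a single dense batch and no padding is
needed.

## Evaluation protocol

ACC, SEN, SPE, PRE and F1 follow the standard confusion-matrix formulas;
TPR/TNR are aliases of SEN/SPE for survival-stratum labeling. A metric
with a zero denominator is reported as explicitly undefined (`None`), never
as 0, so averages over small folds are not silently distorted; undefined
values are dropped from fold averages. Multiclass results are summarized as
overall accuracy with optional one-vs-rest per-class breakdowns.

Cross-validation is stratified k-fold (k ∈ {2, 3, 10} supported, any k ≥ 2
accepted), repeated with re-randomized folds per run via run-indexed seeds;
the summary is mean ± sd over runs of the per-run fold means. Stratification
keeps every class present in every training split, which class modeling
requires.

## Synthetic data

The generator emulates class-separable texture at desk scale, with three
texture families: sinusoidal gratings `0.5 + 0.4 sin(2π m/period + phase)`
varying along rows (so the column-stacked signal is periodic with the
designed period — at fs = 300 Hz, period 6 px ⇒ a 50 Hz tone),
checkerboards, and Gaussian random fields with power-law spectra
(amplitude ∝ f^(−exponent/2), random phases; exponent 0 is white noise).
Per-image phase and noise are jittered from a seeded generator;
everything is deterministic given the seed. The default two-class
condition is gratings of period 6 vs 16 px with noise sd 0.05, 40 images
per class at 64 × 64 px — small enough that a full repeated tenfold
cross-validation runs in well under a minute, while the per-image mean-IF
distributions of the two classes do not overlap.

What passing these experiments shows: the pipeline's plumbing, feature
definitions, determinism, and the classifier's ability to learn separable
sequential structure under class modeling. What it does not show: that the
features separate real stained-tissue classes. Real histology has spatially
heterogeneous, non-stationary texture, staining variability, and no single
dominant spatial frequency; the synthetic textures model none of these.
Results on the synthetic benchmark are an integrity check of the method's
implementation, not evidence of clinical performance.

## Known limitations

* CPU-only, desk-scale training; no GPU path, no attention, no pre-trained
  weights.
* FCM per segment is the dominant feature-extraction cost; very large
  images (signals of millions of samples) would need coarser segmentation
  or subsampling.
* The single max–min composition follows the printed definition; whether a
  full transitive closure should be applied is left as the opt-in.
* One-sided spectra assume real-valued signals; complex inputs are out of
  scope, as are crisp recurrence plots and other recurrence quantification
  measures.
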