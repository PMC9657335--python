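# Methods

## Problem and scope

`emglesion` implements a binary classification study on intramuscular EMG:
distinguishing muscle activity recorded before an experimental spinal cord
lesion (class 0) from activity recorded after it (class 1). Two classifiers
are compared under identical preprocessing: a k-nearest-neighbors model on
four classical amplitude features, and a compact 1-D convolutional network
operating directly on normalized signal windows. Because no public EMG
dataset with this pre/post-lesion structure exists, the package ships a
synthetic generator that emulates the generative structure such recordings
are understood to have, and every quantitative result in the test suite is
computed on that synthetic data.

## Synthetic EMG model

A recording is the linear superposition of motor unit potential trains
(MUPTs) plus additive noise:

    x(t) = Σ_u Σ_j w_u(t − t_{u,j}) + ε(t),   ε(t) ~ N(0, σ²)

- **Potential template** `w_u`: first derivative of a Gaussian, a minimal
  biphasic surrogate for a motor unit potential — smooth, band-limited,
  mean-subtracted, peak-normalized to the unit's amplitude. Template
  duration is drawn per unit from U(4, 12) ms, amplitude from U(0.2, 1.0)
  signal units, typical of tonically active intramuscular recordings.
- **Firing model**: inter-pulse intervals are Gaussian perturbations of the
  mean interval 1/rate with coefficient of variation 0.15, truncated at a
  1 ms floor (absolute refractoriness). Mean rates are drawn from
  U(8, 20) Hz. This captures "repeated firing with physiological jitter"
  without a full point-process model.
- **Noise**: white Gaussian, σ = 0.05 signal units by default — a clearly
  audible but non-dominant background relative to unit amplitudes ≤ 1.
- **Lesion regime**: the post-lesion class is produced by keeping a
  `recruitment_fraction` of the unit pool active and scaling firing rates
  and amplitudes. The default regime (0.5, 0.8, 0.6) encodes the expected
  direction of lesion effects — fewer recruited units, slower firing,
  smaller potentials — and produces clearly separable classes. Whether real
  post-lesion EMG shows *reduced* rather than merely *altered* power is an
  assumption here; the regime is fully configurable, and the identity
  regime (1, 1, 1) reproduces pre-lesion statistics exactly.
- **Sampling rate**: 1000 Hz by default. The analysis window is 1000 ms and
  the network input is 1000 samples, implying one sample per millisecond;
  1000 Hz also satisfies Nyquist for the 450 Hz band edge. **Note:** this
  rate is an inference from the window/input sizes, not a measured
  property of any particular telemetry system.

Every operation is a pure function of its arguments including the seed;
dataset generation derives per-recording seeds from a master seed.

## Conditioning chain

In narrative order, each recording undergoes:

1. **Band-pass**: Butterworth design of prototype order 4 with cut-offs
   10–450 Hz (the `butter(4, [10 450])` idiom), applied forward and
   backward so the net phase is zero. Zero-phase filtering uses
   `scipy.signal.sosfiltfilt` with its default odd-reflection edge padding,
   the standard transient-suppression choice.
2. **Notch**: IIR notch at 60 Hz, quality factor Q = 30 (narrow stop band;
   neighbors at ±30 Hz pass within 10 %), also forward–backward.
3. **Segmentation**: disjoint consecutive 1000-sample windows; a trailing
   remainder shorter than one window is discarded.
4. **Balancing**: random over-sampling of the minority class up to the
   majority count (all original rows retained; duplicates drawn uniformly
   with replacement). With the default generator both classes are equal
   sized and this is a no-op, which also means no duplicated rows can leak
   across the later split.
5. **Normalization**: per-segment min–max scaling to [0, 1]. Per-segment
   (rather than global) scaling matches the network's fixed input range,
   removes slow amplitude drift between recording days, and sidesteps any
   train/test leakage of scaling parameters. A constant window maps to all
   zeros.
6. **Split**: stratified 80:20 at segment level, `round(0.2·n)` test rows
   per class. Segment-level splitting can place windows of one recording
   in both sets; `split_by_recording=True` gives the leakage-free variant.

## Feature-based arm (kNN)

Four amplitude features per segment, computed on the normalized windows
(the narrative order of the chain; configurable to raw segments):

- **area** — integrated rectified value Σ|x_i|;
- **RMS** — √(mean x_i²);
- **turns** — local extrema whose amplitude differs from the previously
  counted turn by more than a threshold. The classical Willison threshold
  of 100 µV is meaningless after min–max normalization, so the default is
  0.1 × the training amplitude range;
- **zero crossings** — thresholded sign changes (threshold 0, exact zeros
  carry the previous sign). On [0, 1]-normalized windows no sign changes
  occur, so this column is constant; the zero-variance rule maps it to 0
  with a warning and classification is carried by the other three
  features. Computing features on pre-normalization segments restores it.

Features are standardized (z-score, population std) then min–max rescaled
to [0, 1], both fitted on training rows only; test rows may fall outside
[0, 1]. kNN uses k = 9, Euclidean distance, exhaustive search; distance
ties resolve to the lower training-row index, and the odd k makes vote
ties impossible.

## Convolutional network

Input 1000 × 1 → conv(32 filters, kernel 5, stride 2) → ReLU → maxpool(2,2)
→ conv(32, 5, stride 2) → ReLU → maxpool(2,2) → conv(64, 3, stride 1) →
ReLU → maxpool(2,2) → dropout 0.1 → conv(128, 3, stride 1) → ReLU →
maxpool(2,2) → dropout 0.1 → global average pooling (128) → dense(100) +
ReLU → dense(1) + sigmoid. Temporal lengths run 1000 → 500 → 250 → 125 →
63 → 63 → 32 → 32 → 16; 49,257 trainable parameters.

- **Padding convention**: "same" padding with ceil-mode pooling everywhere
  is the only convention that reproduces this shape sequence (e.g.
  125 → 63 through a stride-2 pool); it is therefore fixed, and
  `derive_shapes`/`count_parameters` expose the arithmetic for inspection.
- **Kernel notation**: the (5, 1)/(3, 1) kernels are 1-D kernels of length
  5 and 3; the trailing 1 is the singleton spatial dimension of a
  single-channel signal.
- **Loss**: binary cross-entropy, natural log, probabilities clipped to
  [1e-7, 1 − 1e-7]. Training back-propagates through the logit
  formulation (gradient `p − x` per instance), which is exact and stable;
  the clipped form is used for reporting.
- **Optimizer**: Adam, learning rate 0.001, batch size 128, β₁ = 0.9,
  β₂ = 0.999, ε = 1e-7 (common framework defaults, pinned in config).
- **Initialization**: seeded uniform fan-in scheme, limit √(6/fan_in);
  biases zero. Weight init, batch shuffling and dropout masks derive from
  three independent streams spawned from the training seed, so runs are
  reproducible on one machine in single-threaded mode.
- **Decision rule**: probability > 0.5 → class 1 (post-lesion); exactly
  0.5 resolves to class 0 (strict inequality for the positive class).
- **Epochs**: the reference configuration is 500 epochs
  (`configs/reference-defaults.yaml`); the package default is 30, which is
  sufficient on the clearly separable default synthetic conditions and
  keeps a full run in the minutes range on one CPU. On the default
  pipeline (1,280 training segments) 30 epochs is 300 optimizer steps;
  convergence at this step count varies by a few points of F-measure
  across seeds, and longer training tightens it.

The network, backward pass and optimizer are implemented directly in NumPy
(im2col convolutions); gradients are verified against central differences
in the test suite. Exact ReLU kinks (pre-activations exactly 0, common
with zero-initialized biases over zero-padded regions) are excluded from
that comparison since the two-sided difference and the subgradient
legitimately disagree there.

## Evaluation

Confusion counts with post-lesion (class 1) positive — detecting the
lesion effect is the clinical question. Five metrics in percent: accuracy,
sensitivity, specificity, precision, F-measure (harmonic mean of precision
and sensitivity). Zero denominators yield 0 with a warning rather than
NaN. Cross-validation is stratified k-fold (default 5) at segment level,
disjoint and exhaustive, with per-fold metrics and mean ± std; the 80:20
single-split mode and the CV mode are both available because hyperparameter
selection and final reporting are distinct concerns.

## Pipeline and reproducibility

`run_pipeline` executes simulate → preprocess → (features → kNN | CNN) →
evaluate, persisting intermediate datasets, the trained model, history
curves, reports and a manifest (config hash, stage seeds, per-file
checksums). Stage seeds are SHA-256 hashes of `(master_seed, stage_name)`,
so changing one stage's randomness never perturbs another. Default sizes —
400 recordings per class, 2 s each at 1000 Hz, i.e. 1,600 segments before
splitting — keep a full run around three to four minutes on one CPU while
leaving the classes' separability statistically unambiguous.

## What the synthetic data does not show

The generator produces stationary, single-channel, linearly superimposed
activity with white noise and a fixed unit pool per recording. Real
intramuscular EMG adds recruitment-threshold dynamics, fatigue, electrode
drift, movement artifact, cross-talk and day-to-day non-stationarity, and
real post-lesion changes need not be a uniform scaling of rates and
amplitudes. Passing results here demonstrate that the pipeline is
implemented correctly and can detect the modelled class contrast; they do
not certify performance on real recordings, and the headline accuracy
measured on synthetic data has no bearing on what the same architecture
achieves on any animal dataset.

## Known limitations

- The turns/zero-crossing thresholds interact with per-segment
  normalization (see above); both thresholds and the feature-input stage
  are configurable.
- Segment-level splitting and CV mirror the reference design but allow
  windows of one recording on both sides; recording-level grouping is
  provided and recommended for leakage-sensitive claims.
- `filtfilt` edge transients are suppressed, not eliminated; gain
  contracts in the tests are asserted on the interior 80 % of samples.
- Training determinism is guaranteed only single-threaded on one machine;
  BLAS threading can introduce tiny nondeterministic reduction orders.
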