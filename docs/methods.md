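# Methods

## Problem and model

The package classifies near-infrared (NIR) absorbance spectra —
331 variables spanning 740–1070 nm, one class label per sample (grain
variety identification is the motivating application) — with a jointly
trained convolutional autoencoder, and benchmarks it against classical
chemometric pipelines.

The network, SpecFuseNet, has three parts sharing one encoder:

* **Spectral encoder** — three blocks (1 → 32 → 16 → 8 channels), each
  `Conv1D(k=3, stride 1, same padding) → BatchNorm → activation →
  FusedECA → SRG`.  Stride 1 with same padding means every layer
  preserves the spectral length m, so the latent code is an 8 × m map
  (2648 features on the default grid).
* **Spectral decoder** — the mirror image with transposed convolutions
  (8 → 16 → 32 → 1), each block carrying the same attention/gating
  pair, closed by an output transposed-conv block.  At stride 1 the
  transposed convolution equals cross-correlation with the
  index-reversed kernel; this equivalence is exercised in the tests
  against the literal summation.
* **Classifier** — `Flatten → Dense(128, activation, L2) → Dense(K,
  softmax)` on the flattened latent code.

**FusedECA** (fused efficient channel attention): global average and
global max pooling each compress the spectral axis to one descriptor
per channel; each descriptor sequence is cross-correlated with a small
shared kernel *along the channel axis* (zero "same" padding, bias
included), squashed with a sigmoid, and the two attention maps are
fused by elementwise maximum before rescaling the input channels.
Setting `fused=False` drops the max-pooling branch and recovers plain
GAP-only ECA (the ablation variant).

**SRG** (spectral residual gate): at every spectral position i the
channel vectors of the trunk x and the residual r are concatenated
(2C), passed through a 2C → h_d → C → 1 multilayer perceptron and a
sigmoid, producing a scalar gate g(i) ∈ (0,1); the output is
x + α·g·r with α a learnable global scale initialised at 1.  Because
the gate lies in (0,1), ‖x̂ − x‖ ≤ |α|·‖r‖ always holds.  Inside an
encoder/decoder block the residual r is the block *input*, projected to
the block's channel count by a width-1 convolution when the counts
differ.  The defining equation is ambiguous about whether the gate is
per-position or one scalar per feature map; the per-position reading is
the default because it is the only one under which all three weight
matrices type-check while letting the gate vary across the spectrum; a
`srg_global_gate` switch averages the gate into the single-scalar
alternative.  MLP biases sit on the first two layers only, so the
initial gate is centred at 0.5.

## Training objective

`L = w₁·MSE(x, x̂) + w₂·CE(y, p) + λ·Σ w_i²` with default weights
w₁ = w₂ = 0.5, λ = 0.01, the L2 term running over convolutional and
dense kernels only (not biases, batch-norm, or attention/gate
parameters).  MSE is the mean over all elements of the batch; CE is
sparse categorical cross-entropy with probabilities clamped at 1e-12.
Optimisers: Adam (β = 0.9/0.999), RMSprop (decay 0.99), plain SGD, and
Adadelta (ρ = 0.95), all at initial learning rate 1e-4, implemented
directly on the package's autograd parameters.  A plateau scheduler
halves the learning rate after five consecutive epochs without a
strictly lower validation loss (min-lr floor 1e-6, no early stopping).
Batch size 32.  Batch normalisation uses momentum 0.99 and ε = 1e-3 in
the order Conv → BN → activation.

The networks run on a small reverse-mode automatic-differentiation
engine over NumPy arrays written for this package
(`specfusenet.autograd`).  The engine is dtype-preserving: reference
and oracle computations run in float64, while the training loop casts
parameters and batches to float32 for speed.  Every primitive's
gradient is validated against central finite differences in the test
suite (tolerance 1e-4 relative, evaluated in float64).

## Preprocessing and cross-validation

Savitzky–Golay first derivative (window 5 points, quadratic local
polynomial), scaled by the wavelength step so the derivative is per nm;
edges use the one-sided polynomial fit (`mode="interp"`), keeping the
variable count at m.  The derivative removes additive baseline offsets
— exactly the artefact the synthetic generator injects.  Per-wavelength
standardisation to zero mean, unit variance (population convention,
divide by n) follows; channels with standard deviation below 1e-12 get
a unit divisor.  Standardisation is fitted on each fold's training rows
only, so no statistic of held-out rows leaks into training.

Stratified k-fold (default k = 5) splitting shuffles each class's rows
with the run seed and deals them round-robin, guaranteeing per-fold
class counts within one of the proportional share; the starting fold
rotates across classes so small classes spread evenly.

Metrics: accuracy, precision, recall, F1 in percent from the confusion
matrix, with per-class scores combined by support-weighted averaging
(a `macro` option exists).  Under support weighting, recall is
identically the accuracy — an invariant asserted in the tests.  Fold
results are reported both pooled (metrics of the summed confusion
matrix) and as the per-fold mean, since either aggregation is a
legitimate summary.

## Baselines

* **PCA + classic classifiers** — PCA is computed from first
  principles: mean-centering, covariance with 1/(n−1), eigendecomposition,
  top-k eigenvectors (k an integer or an explained-variance fraction,
  default 0.99), with each component's largest-magnitude coordinate made
  positive for reproducible signs.  Scores feed linear SVM (C = 0.1,
  max 200 iterations, balanced class weights), RBF SVM (C = 1),
  random forest (200 trees, balanced), or XGBoost (multi:softmax,
  200 estimators, learning rate 0.1) — all consumed from
  scikit-learn/xgboost with those settings.
* **Encoder features + classic classifiers** — the flattened latent
  code replaces PCA scores; the network is trained inside each fold on
  that fold's training rows only, so the comparison is leakage-free and
  shares the PCA pipeline's fold splits for a paired reading.
* **Dense autoencoder (AE)** — a fully connected
  m → 256 → 128 → 64 → 128 → 256 → m autoencoder with the same
  classifier head on the 64-d latent code and the same joint loss.
  The layer sizes are this package's own choice for a plain-AE
  comparison point and are recorded in its outputs.
* **Sparse convolutional autoencoder (CSAE)** — the convolutional
  backbone without attention/gating, adding L1 penalties on the encoder
  conv kernels (default 1e-4) and on the latent activations
  (default 1e-5; per-sample sum of absolute activations, batch-averaged).
  With both coefficients zero it is weight-for-weight the plain CAE at
  initialisation.
* **Module ablation** — CAE, CAE+ECA (GAP-only), CAE+FusedECA, and
  CAE+FusedECA+SRG cross-validated on shared fold splits with all other
  settings identical.

## Synthetic data

The generator emulates multi-class NIR spectra: each class template is
a shared set of Gaussian absorption bands (default 4 bands, centers
uniform in 760–1050 nm, widths 10–60 nm, amplitudes 0.2–1) whose
centers are shifted per class by normal offsets with standard deviation
`class_separation` (nm).  Each sample multiplies its template by
(1 + scatter), adds a random degree-2 polynomial baseline — giving the
derivative preprocessing real work — and white noise.  Defaults:
10 classes × 50 samples (the shape of the smallest real grain set),
scatter 5%, baseline scale 0.1, noise 0.01, separation 16 nm.  The
separation default was calibrated once so that a PCA + linear-SVM
reference pipeline exceeds 95% accuracy — i.e. the "well-separated"
regime is defined by a model-independent oracle, not by the network
under test.  With `class_separation = 0` the class templates coincide
exactly and any classifier can only reach chance; this is the
generator's negative control.

What the generator does **not** emulate: instrument response functions,
wavelength-dependent noise, water-band interference, chemically
correlated band intensities, or inter-cultivar structure beyond rigid
band shifts.  Passing tests therefore demonstrate that the pipeline
recovers smooth band-position class structure under baseline and
scatter nuisance — not that it attains any particular accuracy on real
grain spectra.

## Problem sizes and numerical choices

Test and acceptance runs train 2–30 epochs on the 500-sample preset
(the reference setup for real data is 300 epochs); at high separation
the model passes 95% validation accuracy well before 30 epochs, so the
recovery experiments use 20–30-epoch folds and the ablation/control
runs use 2-epoch folds, where only completeness and above-chance
behaviour are asserted.  Other numerics: softmax is computed with max-shift
stabilisation; ties in max-pooling gradients split evenly (measure-zero
for continuous data); the ECA channel convolution and the SRG MLP are
evaluated as width-1 convolutions to keep the batch layout contiguous;
Adam/RMSprop use ε = 1e-7.

## Known limitations

* Single-CPU NumPy training: practical up to a few thousand spectra;
  no GPU path.
* The ECA convolution's padding/bias and the SRG residual source inside
  blocks are under-determined by the defining equations; the choices
  above (zero-pad "same" + bias; block-input residual with width-1
  projection) are declared conventions, each behind a config flag where
  an alternative reading exists.
* Checkpoints store raw parameter arrays keyed by module path; loading
  requires the same architecture configuration.
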