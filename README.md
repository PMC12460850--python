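# specfusenet

Attention-gated 1-D convolutional autoencoder for classifying
near-infrared (NIR) absorbance spectra, with the classical chemometric
pipelines it is meant to be compared against.  The motivating
application is grain-variety identification from portable-spectrometer
scans (331 variables, 740–1070 nm), but nothing in the package is
specific to grain: any sample × wavelength table with class labels fits.

## The model

SpecFuseNet trains one encoder for two objectives at once:

```
x ──▶ encoder ──▶ latent (8 × m) ──▶ decoder ──▶ x̂        (reconstruction)
                     └────▶ flatten ──▶ dense ──▶ softmax  (classification)

L = w₁·MSE(x, x̂) + w₂·CE(y, p) + λ·Σ wᵢ²,   w₁ = w₂ = 0.5, λ = 0.01
```

Each encoder block is `Conv1D(k=3, same) → BN → ELU → FusedECA → SRG`
with channel widths 32 → 16 → 8; the decoder mirrors it with transposed
convolutions.  The two blocks that distinguish the architecture:

* **FusedECA** — channel attention from *both* global average and
  global max pooling: each pooled descriptor is convolved along the
  channel axis (kernel 5) and squashed by a sigmoid, and the two
  attention maps are fused by elementwise maximum,
  `s = max(σ(Conv1D(z_GAP)), σ(Conv1D(z_GMP)))`, then applied
  multiplicatively per channel.
* **SRG** — a gated skip connection,
  `x̂ = x + α·σ(W₃(W₂·Act(W₁·[x; r])))·r`, with a per-position scalar
  gate and a learnable global scale α (init 1), so the network decides
  per wavelength how much of the residual to re-inject.

Preprocessing follows standard chemometric practice: Savitzky–Golay
first derivative (window 5, quadratic), per-wavelength standardization
fitted on training folds only, stratified 5-fold cross-validation.
Baselines: PCA (+ linear/RBF SVM, random forest, XGBoost), encoder
features + the same classifiers, a dense autoencoder, a sparse
convolutional autoencoder, and the module ablation
CAE → +ECA → +FusedECA → +SRG.

The networks run on a compact NumPy autograd engine included in the
package (`specfusenet.autograd`) — no deep-learning framework needed;
gradients are finite-difference-checked in the test suite.

## Worked example

The package ships a synthetic-spectra generator (Gaussian absorption
bands with class-specific center shifts, multiplicative scatter,
polynomial baseline drift, white noise), so everything is runnable
without any download:

```python
import specfusenet as sf

ds = sf.generate(sf.sorghum_like(seed=0))        # 500 spectra, 10 classes
rep = sf.cross_validate(ds, k=5, seed=0, epochs=30)
print(f"accuracy {rep.accuracy:.1f}%  per-fold mean "
      f"{rep.fold_mean['accuracy']:.1f}%")
pca = sf.pca_pipeline(ds, "svm_linear", k=5, seed=0)
print(f"PCA+SVM baseline {pca.accuracy:.1f}%")
```

prints

```
accuracy 98.0%  per-fold mean 98.0%
PCA+SVM baseline 100.0%
```

i.e. on well-separated synthetic bands the jointly trained network
recovers the class structure almost perfectly after 30 short epochs
(the linear baseline is exact here because the synthetic classes are
linearly separable by construction — the network's value shows on data
where they are not).  Dropping `class_separation` to 0 makes the class
templates identical and the same pipeline lands at chance (10%).

The same workflow is available from the shell:

```bash
specfusenet synthesize --preset sorghum-like --seed 0 -o out/
specfusenet train   --data out/synth.csv --epochs 30 -o out/
specfusenet ablate  --data out/synth.csv --epochs 5  -o out/
specfusenet sweep   --data out/synth.csv --epochs 5  -o out/   # 4×4 optimizer/activation grid
specfusenet baseline --data out/synth.csv --kind svm_linear -o out/
specfusenet embed   --data out/synth.csv -o out/               # t-SNE latent maps
```

Every run directory receives reports (JSON/CSV), confusion-matrix
heatmaps, and a resolved-config snapshot sufficient to re-execute the
run.

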