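# Methods

## Problem setting

`swirclass` classifies precooked pasta products from Vis–SWIR reflectance
spectra (350–2500 nm at 1 nm, 2151 variables per spectrum). The emulated
study design has two products (class 1 = Pennette72, class 0 = Mezze Penne),
six physical samples per product, two physical states (frozen, thawed), and
50 replicate spectra per sample per state — 1200 spectra in total, 600 per
state. Spectra of thawed samples separate the two products much more clearly
than frozen ones: the class difference is a broadband reflectance offset over
1300–2500 nm that is large after thawing and nearly absent when frozen.

## Preprocessing

*Standardization* is the per-variable z-score S = (x − μ)/σ with the
**population** standard deviation (divide by n), matching the common
standard-scaler convention. Variables with σ = 0 map to 0 rather than
dividing by zero. *PCA* is the bilinear decomposition X = T·Pᵀ + E with
orthonormal loadings P (m × k) ordered by explained variance; the default
retains k = 100 components. The PCA stage runs on standardized spectra.

Both transforms are fitted on the **training split only** by default; this
avoids information leakage into the test metrics. Whether the original
acquisition protocol pooled the data before fitting is not documented;
fitting scope is therefore a pipeline decision here, not a claim about the
source protocol.

*Systematic split.* The 7:3 train/test split is deterministic: within each
stratum (product class × physical state, in file order) indices are walked in
blocks of ten and, at train fraction 0.7, index i goes to the test set iff
i mod 10 ≥ 7. Strata of size 300 give exactly 210/90, so each physical state
yields 420 training and 180 test spectra. Because replicate spectra are
interleaved, the same physical samples appear on both sides of the split —
the design evaluates replicate-level generalization, not sample-level
generalization.

## Models

All deep models are implemented in `swirclass.nn`, a compact numpy layer
library with hand-derived backpropagation (1-D convolution via im2col,
per-channel batch normalization, ReLU, max pooling, dense, dropout, LSTM with
full backpropagation through time, softmax cross-entropy, Adam). Every
layer's gradient is verified against central finite differences in the test
suite, and the LSTM cell against an independent elementwise oracle.
Parameters default to float32 for training throughput; float64 is available
for verification work.

* **cnn** — a modified one-dimensional AlexNet: five valid (unpadded)
  convolutions with (filters, kernel, stride) = (64,11,4), (64,5,1),
  (92,3,1), (92,3,1), (64,3,1); batch normalization before the first three;
  ReLU after each; **no pooling**; one hidden fully connected layer
  (width 128, ReLU, dropout 0.5) and a two-class output layer.
* **lstm** — the spectrum read as an ordered sequence (one reflectance value
  per step) by a single LSTM with hidden size 10; dropout 0.3 on the final
  hidden state; two-class output. Gates act on the concatenation
  [h_{t−1}, x_t]; the candidate memory uses tanh and the forget/update/output
  gates the logistic sigmoid; C_t = f_t∗C_{t−1} + i_t∗C̃_t and
  h_t = o_t∗tanh(C_t).
* **cnn_lstm** — the hybrid: the CNN's convolutional stack (without
  flatten/FC head) emits a feature sequence — one 64-channel vector per
  position of the reduced spectral axis (13 steps for a 100-variable input,
  526 for the canonical grid) — which the LSTM consumes; dropout 0.3, then
  the output layer. The sequence-axis = spectral-positions reading is a
  design decision; the alternative (channels as steps) is not exposed.
* **alexnet1d / alexnet_lstm** — classical references keeping max pooling
  (size 3, stride 2 after conv layers 1, 2, 5) and two hidden FC layers
  (256, 128, dropout 0.5 each).

Training uses mini-batch Adam, batch size 32, learning rate 0.001, softmax
cross-entropy, argmax prediction. The epoch count defaults to 100 and is
config-exposed; the heavy evaluation runs documented below use far fewer
because the synthetic task converges within one to three epochs.
Initialization: He-normal for conv/dense, uniform ±1/√H for LSTM weights with
the forget-gate bias at 1 (a standard long-memory initialization). Batch
normalization keeps running statistics (momentum 0.1) for inference;
inference-mode forward passes are deterministic.

Classical baselines (KNN, decision tree, Gaussian naive Bayes, SVM) delegate
to scikit-learn with library defaults, recorded per row of the benchmark
grid.

## Evaluation

With class 1 as positive: accuracy = (TP+TN)/total, precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2PR/(P+R). A metric whose denominator is zero is
reported as absent with a reason, never silently as 0. The benchmark grid
reports macro averages (unweighted mean of the two per-class values);
accuracy is class-symmetric and passes through. The recall denominator is
the standard sensitivity form; a source formulation circulating with a
TN+FN denominator is treated as a typographical error since it is not a
recognized metric and contradicts the harmonic-mean F1 relation.

## Synthetic data generator

Each spectrum = continuum − absorption bands + state effects + class offset
+ sample effect + noise, clipped to [0, 1]:

* continuum: gentle quadratic from ≈0.45 at 350 nm to ≈0.65 at 2500 nm;
* bands: Gaussian dips at 1450 nm (depth 0.15) and 1940 nm (depth 0.20),
  width 40 nm — the water absorption features of moist food;
* frozen state: band depths × 1.3, plus +0.02 reflectance over 350–1450,
  1600–1850 and 2100–2400 nm (ice reflects more broadband);
* class offset on class 1 over 1300–2500 nm: +0.03 thawed, +0.005 frozen —
  the built-in encoding of "thawed products separate, frozen ones barely do";
* per-sample baseline shift ~ N(0, 0.01), shared by all replicates of a
  sample (and across its two states), making replicates correlated;
* per-point Gaussian noise, sd 0.01.

All magnitudes are configuration defaults chosen to produce plausible
reflectance levels and the qualitative orderings above; none is a measured
value. The generator is deterministic for a fixed seed.

**What the generator does not emulate.** Real reflectance spectra are smooth
and their replicate-scan noise is wavelength-correlated (the source
instrument has 3–10 nm optical resolution, so independent noise at 1 nm
spacing overstates the effective noise dimensionality); real between-sample
variation is spectrally structured rather than a flat baseline shift; and
real class differences spread over many principal components. Consequences
for interpreting results are discussed under Limitations.

## Problem sizes used in the shipped evaluations

The seed-replicated benchmark (5 seeds × 2 states × {cnn, lstm, cnn_lstm})
runs on standardized full-resolution spectra (2151 variables, 420 train /
180 test per state) for 3 epochs per model; on this synthetic task the
deep models reach their plateau within 1–3 epochs, so longer schedules only
add run time (and, for the hybrid in the frozen condition, more
memorization — see Limitations). Seed-to-seed variability is real: on the
thawed data the CNN reaches 100% on every seed while the hybrid stalls near
91% on some seeds (seed-mean ≈ 96%), another face of the memorization effect
described below. The full default pipeline (simulate →
split → standardize → PCA(100) → CNN–LSTM, 100 epochs) runs in a few
minutes on one CPU core.

## Known limitations

* **PCA noise-score inflation.** With 420 training spectra of 2151
  standardized variables, the trailing principal components fit the
  training replicates' white noise: training scores on those components have
  several times the variance of test scores. Models that key on
  high-variance noise components therefore see a systematic train/test shift.
  This is a property of fitting k = 100 components to n = 420 white-noise-rich
  samples, not of the PCA implementation.
* **Hybrid memorization under weak class signal.** When the class offset is
  small relative to replicate noise (the frozen-like condition), the
  CNN→LSTM hybrid tends to co-adapt its convolutional stack to memorize
  replicate-specific noise before the recurrent head extracts the class
  signal; the plain CNN's dense head finds the separating contrast first and
  generalizes. As a result, on this generator the seed-mean ordering
  CNN–LSTM ≥ CNN does **not** hold: the hybrid trails the CNN in the frozen
  condition and on the stalling thawed seeds. In controlled ablations the
  effect disappears when the variance of the uninformative input dimensions
  is small — the regime real smooth spectra occupy — so conclusions about
  the hybrid's advantage on real data cannot be drawn from this generator.
* Replicate-interleaved splitting means reported accuracies measure
  within-sample generalization; sample-level (leave-sample-out) validation
  is not part of the emulated design.
* The generator's flat sample effect and white noise are the main realism
  gaps; both are config-exposed (`sample_effect_sd`, `noise_sd`).
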