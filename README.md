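# swirclass

Classification of Vis–SWIR (350–2500 nm) reflectance spectra of food
products with a one-dimensional CNN–LSTM hybrid, classical chemometric
baselines, and a fully synthetic spectrum generator for end-to-end testing.

## Who this is for

Chemometricians and food-quality researchers who want a tested, dependency-
light reference implementation of a spectral deep-learning pipeline: tabular
spectra I/O, z-score standardization, PCA feature extraction (X = T·Pᵀ + E),
a deterministic systematic 7:3 train/test split, a modified 1-D AlexNet-style
CNN, a spectrum-sequence LSTM, their hybrid, and binary evaluation metrics —
all runnable without any proprietary data, against a seeded simulator of a
two-product × two-physical-state (frozen vs thawed) pasta study design.

## The models in brief

* **Standardization** S = (x − μ)/σ per wavelength (population σ), then
  optionally **PCA** retaining k = 100 components of the 2151-variable
  spectra.
* **1-D CNN**: five valid convolutions — (filters, kernel, stride) =
  (64,11,4), (64,5,1), (92,3,1), (92,3,1), (64,3,1) — batch-normalized before
  the first three, ReLU throughout, no pooling, one hidden fully connected
  layer (dropout 0.5), two-class output.
* **LSTM** (hidden size 10, dropout 0.3) over the spectrum as an ordered
  sequence, with the gated cell update
  C̃ₜ = tanh(W_c·[h_{t−1}, xₜ] + b_c), fₜ/iₜ/oₜ = σ(W·[h_{t−1}, xₜ] + b),
  Cₜ = fₜ∗C_{t−1} + iₜ∗C̃ₜ, hₜ = oₜ∗tanh(Cₜ).
* **CNN–LSTM**: the conv stack's output — a sequence of 64-channel feature
  vectors along the reduced spectral axis — feeds the LSTM.
* Training: Adam, learning rate 0.001, batch size 32, softmax cross-entropy.
* Metrics: accuracy, precision, recall (TP/(TP+FN)), F1, macro-averaged over
  the two classes; label 1 = Pennette72, 0 = Mezze Penne.

The neural layers are implemented in numpy with hand-derived backpropagation
(`swirclass.nn`) and are verified against finite differences and independent
oracles in the test suite. See `docs/methods.md` for assumptions, defaults,
and known limitations.

## Worked example

```python
from swirclass.synthgen import GeneratorConfig, generate_dataset
from swirclass.spectra_io import subset_by_state
from swirclass.preprocess import systematic_split, fit_standardizer, apply_standardizer
from swirclass.dl_models import ModelSpec, build_model
from swirclass.train_eval import TrainConfig, train_classifier, predict, evaluate_predictions

ds = generate_dataset(GeneratorConfig(seed=1))        # 1200 spectra, 2151 variables
thawed = subset_by_state(ds, "thawed")                # 600 spectra
train, test = systematic_split(thawed)                # 420 / 180, deterministic
std = fit_standardizer(train)
Xtr, Xte = apply_standardizer(train, std).X, apply_standardizer(test, std).X

model = build_model(ModelSpec(kind="cnn_lstm"), input_len=2151, seed=1)
train_classifier(model, Xtr, train.labels, TrainConfig(epochs=3, seed=1))
report = evaluate_predictions(test.labels, predict(model, Xte))
print(f"accuracy={report.accuracy:.4f} precision={report.precision:.4f} "
      f"recall={report.recall:.4f} f1={report.f1:.4f}")
```

Output:

```
accuracy=1.0000 precision=1.0000 recall=1.0000 f1=1.0000
```

The thawed state carries a large between-product reflectance offset over
1300–2500 nm, so the hybrid separates the two pasta products perfectly on the
held-out replicates; the same experiment on the frozen subset (offset 0.005
instead of 0.03) is markedly harder.

## Command line

```bash
swirclass simulate --seed 1 --out spectra.csv
swirclass split --input spectra.csv --train-out train.csv --test-out test.csv
swirclass preprocess --train train.csv --test test.csv --processing pca --out-dir feats/
swirclass run -c config.yaml --out-dir run/         # full pipeline + manifest
swirclass benchmark --models nb,svm,cnn --processings standardization --out grid.csv
```

Every pipeline run writes `metrics.csv`, fitted transforms, a model
checkpoint, the per-epoch training log, and a `manifest.json` from which the
run can be reproduced exactly.

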