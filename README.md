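# akscreen

Benchmarking a shallow convolutional network against classical
machine-learning pipelines for recognizing **actinic keratosis** (AK) — a
common precancerous skin lesion — in dermoscopy images, where it is easily
confused with **benign keratosis** (BK).

Deep CNNs dominate dermoscopy classification, but keratosis texture is
comparatively simple, and a small network can match or beat deep models on
this task while training in CPU minutes. `akscreen` provides that shallow
network, the classical baselines it is compared against, and the
evaluation protocol, all reproducible from a single seed:

* **Shallow CNN** (NumPy, seeded, bit-reproducible):
  conv 6@5×5 → LeakyReLU(0.01) → maxpool 2×2 → conv 16@5×5 → LeakyReLU →
  flatten(16384) → dense 120 → dropout 0.5 → dense 2 → softmax, trained
  with momentum SGD (μ=0.9, η=1e-4, batch 10, L2 5e-4) on 64×64×3 inputs.
* **Preprocessing**: minority-class augmentation (original + 90° rotation +
  horizontal/vertical flips = ×4), histogram equalization, RGB→CIELAB,
  bilinear resize to 64×64 with [0,1] scaling.
* **Classical baselines**: 900-dimensional HOG descriptor (200×200 image,
  32×32 cells, 2×2-cell blocks, 9 unsigned bins) feeding SVM, random
  forest, and k-NN.
* **Evaluation**: stratified 10-fold cross-validation with Acc, Sens, Spec,
  Prec, MCC and trapezoidal ROC/AUC; augmentation applied inside each fold
  to training data only (no leakage of flipped copies into test sets).
* **Synthetic data**: a seeded generator of two-class lesion-like images
  (class-dependent texture frequency and lesion redness) with a
  `separation` knob from 0 (identical classes — chance level) to 1 (easy),
  so the whole pipeline runs and is tested without any download. Real
  HAM10000-dialect data (`image_id,dx` manifest with `akiec`/`bkl` codes)
  loads through the same interface.

All estimators follow scikit-learn conventions (`fit` / `predict` /
`predict_proba` / `transform`) and compose with `sklearn.pipeline`.

## Worked example

```python
import akscreen as ak

config = ak.RunConfig(synthetic=True, n_per_class=30, image_size=48,
                      separation=1.0, folds=5, epochs=10,
                      models=("cnn", "svm"), seed=7)
result = ak.run_benchmark(config, "bench_out")
print(result["report"][["model", "Acc", "Sens", "Spec", "MCC", "AUC"]]
      .to_string(index=False))
```

prints

```
model      Acc     Sens  Spec      MCC      AUC
  cnn 0.816667 0.933333   0.7 0.665664 0.911111
  svm 1.000000 1.000000   1.0 1.000000 1.000000
```

Each row is the mean over the 5 cross-validation folds. At this deliberately
tiny budget (30 images per class, 10 epochs) the HOG+SVM baseline already
separates the classes perfectly, while the CNN — trained from scratch on 48
images per fold — reaches AUC 0.91; at the study scale (200 per class, 30
epochs) the CNN's cross-validated accuracy and AUC both reach 1.0, which is
what `scripts/acceptance.py` recomputes. Lowering `separation` toward 0
drives every metric to chance (Acc ≈ 0.5, MCC ≈ 0, AUC ≈ 0.5).
`bench_out/` receives
`report.csv` (deterministic metric means), `report.json` (per-fold detail
with training times), per-model ROC point files, the resolved
`config.json`, and a log. Rerunning with the same config reproduces
`report.csv` byte for byte.

The same run from the shell:

```sh
akscreen benchmark --synthetic --out bench_out --seed 7 --folds 5 \
    --epochs 10 --models cnn,svm --set n_per_class=30 --set image_size=48
```

Other commands: `akscreen synth` (write a synthetic dataset + manifest),
`features` (HOG matrix to CSV), `train` (fit and checkpoint the CNN),
`predict` (class probabilities for one image), `evaluate` (metrics of a
checkpoint on a manifest).

## Layout

```
src/akscreen/
  synthetic.py    seeded two-class lesion-image generator + manifest writer
  datasets.py     LabeledImageSet container, HAM10000-dialect manifest I/O
  preprocess.py   augmentation, equalization, CIELAB, ImageStandardizer
  cnn.py          ShallowCNNClassifier (NumPy forward/backward, momentum SGD)
  hog.py          HOG descriptor + HOGFeaturizer transformer
  baselines.py    SVM / random forest / k-NN with a uniform scoring contract
  evaluate.py     confusion metrics, MCC, ROC/AUC, stratified k-fold CV
  benchmark.py    RunConfig + run_benchmark orchestration
  cli.py          `akscreen` command-line entry point
docs/methods.md   model, conventions, design choices, limitations
```
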