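# emgmc

Multi-channel correlation analysis of surface electromyography (sEMG)
signals: wavelet-threshold denoising, inter-channel correlation features,
and a stacking ensemble classifier — with a synthetic multi-channel EMG
generator so the entire pipeline can be exercised and verified without any
external recordings.

## Who this is for

Researchers working on sEMG-based movement/gesture recognition who want a
reproducible reference implementation of correlation-based multi-channel
features. sEMG electrodes pick up crosstalk from neighboring muscles, so
the *dependence structure between channels* carries information about which
muscles are co-activating — often more robustly than per-channel amplitude
features, which fluctuate with force and speed.

## The method

**Denoising.** Each channel is decomposed with a multilevel orthogonal
discrete wavelet transform (default `db4`, 4 levels) and the detail
coefficients are shrunk with one of three rules. With threshold λ (default:
the per-level universal threshold λ_j = σ̂_j √(2 ln N_j), σ̂_j from the
median absolute deviation):

- hard: keep C if |C| ≥ λ, else 0
- soft: sign(C)·max(|C| − λ, 0)
- improved (control coefficient a, default 0.3):

```
C − λ + a·e^λ − a        C ≥ λ
a·|e^C − 1|              −λ ≤ C < λ
C + λ − a·e^{−λ} + a     C ≤ −λ
```

The exponential transition is continuous at ±λ and converges to the soft
rule as a → 0 for |C| ≥ λ, while shrinking soft-thresholding's bias on
large coefficients. The literal rule is not odd-symmetric (negative
coefficients inside the band map to positive values); `improved_odd`
applies it to |C| and restores the sign. Both are provided.

**MC features.** For an M-channel recording, every unordered channel pair
(i, j) contributes two numbers:

- Lin's concordance correlation coefficient (linear dependence),
  ρ = 2s_xy / (s_x² + s_y² + (x̄ − ȳ)²), population moments;
- copula-entropy mutual information (nonlinear dependence): map both
  series to pseudo-observations Û = rank/(N+1) and estimate
  I(X;Y) = −H_c(u, v) with a k-nearest-neighbor (Kozachenko–Leonenko)
  entropy estimator, k = 3, in nats. Rank-based, hence exactly invariant
  under monotone transforms, and no joint density is ever estimated.

Concatenated in row-major pair order this gives the length-M(M−1) MC
feature vector, z-normalized per dimension with training-set statistics.
Time-domain baselines (MAV, ZC, WL, SSC) are included for comparison.

**Classification.** A stacking ensemble: XGBoost, KNN, random forest and
Gaussian naive Bayes produce out-of-fold predicted class probabilities via
internal stratified 5-fold splitting; a multinomial logistic-regression
fuser is trained on those meta-features. Reports: accuracy, macro
precision/recall/F1, and the multiclass Matthews correlation coefficient.

## Worked example

Simulate a 4-class, 4-channel dataset (25 recordings per class, 2048
samples at 1000 Hz, class identity encoded in the inter-channel coupling),
denoise, extract MC features, and run stratified 5-fold cross-validation:

```
$ emgmc run --classes 4 --channels 4 --samples 2048 --per-class 25 \
            --knn-k 5 --seed 7 --out runs/demo
mean CV accuracy 1.0000
outputs in runs/demo
```

`runs/demo/report.json` then contains the across-fold means

```json
{"accuracy": 1.0, "precision": 1.0, "recall": 1.0, "f1": 1.0,
 "mcc": 0.9999999999999998, "n_folds": 5}
```

i.e. with class-specific coupling matrices the MC features are separable
enough that the stack classifies every held-out recording correctly; the
MCC of ~1 confirms this is not a majority-class artifact. The same run is
available library-side via `emgmc.run_pipeline(PipelineConfig(...))`, and
the individual stages via `emgmc simulate`, `emgmc denoise`,
`emgmc features`, `emgmc train`, `emgmc evaluate`.

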