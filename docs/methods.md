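# Methods

## Signal model and the synthetic generator

Surface EMG under uneven force is non-stationary; the generator uses the
standard amplitude-modulation description y(t) = c(t)·m(t), where m(t) is a
zero-mean unit-variance Gaussian carrier and c(t) a contraction-degree
envelope. Three envelopes are provided: `constant` (steady contraction),
`ramp` (linearly increasing force, 0.2 → 1.0), and `burst` (a Gaussian
contraction burst of width N/6 over a 0.1 baseline; the default, as the
most clearly non-stationary case). Spectral energy is concentrated in the
5–200 Hz band of real sEMG by an optional zero-phase 4th-order Butterworth
band-pass (default on, sampling rate 1000 Hz).

The single-channel model says nothing about how M channels relate, but the
features under study live entirely in inter-channel dependence, so the
generator makes dependence the carrier of class identity: per class, M
independent modulated carriers are mixed by a full-rank M×M coupling matrix
(default: I + 0.9·W with W standard normal, redrawn until the condition
number is < 1000), giving each class its own covariance — hence CCC —
signature. Optional monotone distortions (cubic, tanh, exp) replace a
target channel with a strictly monotone function of a source channel,
creating exact functional dependence that copula MI detects at full
strength while CCC under-reports. Additive white Gaussian noise is scaled
to the *empirical* signal power per channel, so a requested SNR is realized
exactly rather than in expectation.

Default study conditions: 4 classes × 25 recordings, 4 channels, 2048
samples. These sizes make a single benchmark run complete in seconds on one
CPU while leaving the classification task non-trivial in feature count
(12-dimensional MC vectors from 100 recordings).

What the generator does *not* emulate: motor-unit action-potential
physiology, electrode geometry, 50/60 Hz mains interference, movement
artifacts, inter-subject variability, or label noise. Passing tests
therefore demonstrate that the pipeline recovers class structure *when that
structure genuinely lives in inter-channel dependence*; they do not certify
accuracy on any particular real recording setup.

All randomness flows from one integer seed through `numpy.SeedSequence`
entropy tuples (seed, class, replicate), so per-recording streams are
independent and every stage is bit-reproducible.

## Wavelet denoising

Discrete, not continuous: thresholding acts on multilevel DWT detail
coefficients, the only computable realization of coefficient shrinkage.
Defaults: `db4`, 4 levels, symmetric boundary extension (configurable);
`db4` is the conventional EMG choice and symmetric extension avoids edge
artifacts. Energy conservation (Parseval) holds only for the orthonormal
periodized variant, which is what the energy tests use.

λ selection defaults to the per-level universal threshold
λ_j = σ̂_j·√(2 ln N_j) with σ̂_j = median(|d_j|)/0.6745 — the canonical
"general threshold" with a MAD noise estimate; a fixed-λ rule is available
for controlled experiments. Approximation coefficients are never
thresholded.

The improved rule's middle branch a·|e^C − 1| is continuous with both outer
branches (equal one-sided limits a·(e^λ − 1) and a·(1 − e^{−λ}) at ±λ) but
not odd: C ∈ (−λ, 0) maps to positive output. It is implemented literally
as `improved`; `improved_odd` = sign(C)·improved(|C|) restores the odd
symmetry a threshold curve is normally drawn with. Empirically, on
synthetic EMG at 10–30 dB input noise, `improved_odd` attains the highest
median output SNR of all four rules, while literal `improved` beats soft
but not hard — the sign flips in the transition band cost it accuracy. Both
are reported by the acceptance script; the default method is `improved`
(the literal rule), and users wanting the best empirical SNR should select
`improved_odd`.

A caveat worth stating: broadband noise-like signals (which EMG carriers
are) overlap the noise in every wavelet band, so universal-threshold
denoising lowers SNR relative to the clean signal at these input levels for
*all* rules; the meaningful comparison is between rules, and downstream the
correlation features are robust enough that denoising is accuracy-neutral
on the synthetic benchmark.

## MC features

CCC uses population (1/N) moments throughout, matching its defining
moment identities; it is exactly symmetric and bounded in [−1, 1]. The 0/0
case (two constant series with equal means) returns 0 with a warning — no
variation is no evidence of agreement.

Copula MI: pseudo-observations Û = rank/(N+1) (average ranks on ties, which
keeps Û strictly inside (0,1)), then I = −H_c with H_c the
Kozachenko–Leonenko k-NN differential entropy (Chebyshev metric, k = 3) of
the pseudo-observation pairs. Units are nats. Known numerical behavior:

- the estimator has a small negative bias on the unit square (boundary
  effect), about −0.04 nats at N = 2000 and k = 3 for independent inputs,
  shrinking with N; MI estimates may therefore be slightly negative for
  independent channels. This is reported as-is rather than clipped.
- rank-basedness makes the estimate *exactly* invariant under strictly
  monotone transforms of either argument, which the tests assert with
  equality, and spares any joint-density estimation.
- N ≥ 20 is required; below that the estimate is meaningless.

Feature layout: [all pairwise CCC, all pairwise MI], pairs in row-major
order (1,2), (1,3), …, (M−1,M); length M(M−1). Normalization is per
dimension, (f − mean)/σ with population σ fitted on the *training* data
only — cross-validation folds never see held-out statistics. Zero-variance
dimensions are flagged and emitted as 0, not NaN.

Time-domain baselines (per channel): MAV = mean |x|; ZC = sign changes
with |Δ| > ε; WL = Σ|Δ|; SSC = slope-sign changes with product > ε;
ε defaults to 0 and is exposed because practical EMG work uses a small
positive value.

## Stacking classifier

Base learners and defaults: XGBoost (100 trees, learning rate 0.01), KNN
(k = 100), random forest (80 trees, depth 5, min 1/leaf, min 2/split),
Gaussian NB (the features are continuous z-scores). Meta-features are
out-of-fold predicted class probabilities (4·K dimensions) from stratified
5-fold internal splitting — probabilities, not hard labels, because they
preserve the base learners' confidence; the fuser is multinomial logistic
regression with default L2 strength. After the fuser is trained the bases
are refit on all training data.

KNN's k must be below every internal training-fold size. At the default
benchmark scale (100 recordings → 64-sample internal training folds) the
k = 100 default is structurally impossible, so benchmark configurations use
k = 5; k remains fully configurable and large-data users can keep 100.

Out-of-fold construction is what prevents meta-feature leakage; the suite
enforces this with a label-shuffle control that must score inside the 95%
binomial interval of chance. Evaluation is stratified k-fold (default 5;
10 available) with normalization and the entire stack fitted inside each
training fold.

## Metrics

Accuracy = trace/total. Precision, recall and F1 are per-class one-vs-rest
and macro-averaged (reported as such); the binary case reads off the
positive class directly. MCC uses the confusion-matrix (Gorodkin)
generalization, which reduces algebraically to the familiar binary formula
at K = 2 — a property the tests check on random matrices. Degenerate 0/0
ratios become 0 with the class flagged in the report.

## Problem sizes and tolerances

Test and acceptance runs use: 20 trials × {10, 20, 30} dB for the denoising
ordering; 100 random pairs at 1e−12 for the CCC oracle; 10 seeds × N = 2000
per correlation level with a 0.1-nat budget for the Gaussian MI oracle
(dominated by the estimator bias above); 1000 random confusion matrices at
1e−12 for the metric formulas; and the 4×4×25×2048 benchmark with a 0.90
accuracy floor, a 0.02 stack-vs-best-base slack (fold sampling noise), and
the binomial chance interval for the shuffle control. Reconstruction
tolerances are 1e−10 (round trip) and 1e−8 relative (energy), far above the
float64 error actually observed (~1e−15).

## Limitations

- The synthetic generator is the only data source; see its non-goals above.
- The copula-MI estimator's boundary bias means near-zero MI values are
  systematically slightly negative; comparisons between pairs are
  unaffected.
- The literal improved threshold's non-odd transition band is kept by
  design; its empirical SNR penalty is documented, not patched.
- Wavelet denoising of broadband EMG-like carriers reduces clean-signal
  SNR at moderate noise levels for all rules; the stage earns its place on
  narrowband or low-frequency content and is configurable/skippable.
- AUC-ROC and t-SNE visualization are deliberately out of the tested core.
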