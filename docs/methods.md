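# Methods

## Model

The classifier maps a non-negative expression vector x_j ∈ R^d (d genes or
gene-set aggregates, d in the hundreds to tens of thousands) to a class
probability while producing a per-feature importance distribution β_j.

**Embedding.** Every feature i carries a fixed vector identity e_i ∈ R^m,
drawn once as i.i.d. N(0, 1/m) from a recorded seed and never trained. The
embedded value of feature i in sample j is the multiplicative interaction
x̂_j⁽ⁱ⁾ = x_ji · e_i. Random embeddings keep the construction free of extra
training and perform comparably to learned ones for this purpose; the
1/√m scale keeps ‖x̂‖ comparable across choices of m.

**Self-attention.** A scorer f_α : R^m → R (one hidden tanh layer, shared
across features) produces α_ji = f_α(x̂_j⁽ⁱ⁾). The score of a feature
depends only on that feature's embedded value — this is what makes the
per-sample importance interpretable feature-by-feature. β_j = softmax(α_j)
(computed with max-subtraction), so β_ji > 0 and Σ_i β_ji = 1. A zero
expression value embeds to the zero vector, so its raw score is the
sample-independent constant f_α(0).

**Representation and head.** f_x : R^m → R^p is a single tanh layer; the
sample representation is the attention-weighted mixture
x̄_j = Σ_i β_ji f_x(x̂_j⁽ⁱ⁾), every coordinate of which lies in (−1, 1).
The head f_y (one hidden layer, batch normalisation, ReLU, sigmoid output)
yields Pr(y_j = 1). Weight sharing across features makes the parameter
count independent of d.

**Training.** Binary log-loss, Adam (lr 1e-3, β = 0.9/0.999), dropout 0.5
on the hidden activations of f_x, f_α and f_y during training only.
Evaluation uses frozen batch-norm running statistics and no dropout, so
per-sample outputs are independent of batch composition. The forward and
backward passes are plain NumPy; gradients are derived analytically
(including through batch normalisation and the softmax Jacobian) and checked
against central finite differences at 1e-4 relative tolerance in the test
suite. All randomness (embedding, initialisation, shuffling, dropout,
validation split) derives from a single config seed, making training
bit-reproducible.

## Parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| m (embedding dim) | 256 | with random embeddings the scorer can only tell features apart through their embedding directions; m must keep d directions nearly orthogonal. 64 was unstable across training seeds on 500-feature cohorts; 256 is stable and still m ≪ d for realistic feature spaces |
| p (representation dim) | 16 | p ≪ m; the head only needs a low-dimensional summary |
| α-scorer hidden width | 32 | small shared scorer; widening to 64 sharpened concentration but flattened within-class signal |
| head hidden width | 8 | minimal capacity on top of p = 16 |
| dropout | 0.5 | applied to all three sub-networks during training |
| epochs / batch | 150 / 16 | smaller batches give more Adam updates per epoch; 50 epochs undertrained at these sizes |
| input scaling | log_center | log1p then subtraction of the per-feature training mean. Centering removes the shared expression baseline that otherwise wastes scorer capacity; *not* dividing by the sd preserves the magnitude signal the attention needs to single out strongly deviating features (full z-scoring left importance diffuse while classification stayed accurate) |
| validation fraction | 0.1 | monitoring only; early stopping is off by default (a 10–15 % validation loss is too noisy at n ≈ 300 to stop on) |

Every entry is a `ModelConfig` field.

## Preprocessing

Size factors are median-of-ratios: per-feature geometric means are computed
in log space over features with strictly positive counts in all samples;
each sample's factor is the median of its count/reference log-ratios
(geometric midpoint for even counts, matching the canonical estimator), and
factors are rescaled to geometric mean 1 so that a normalised matrix
re-estimates unit factors exactly. Gene sets (GMT) are intersected with the
measured feature universe *before* the minimum-size test (default 10
members), since membership outside the assay is unobservable; aggregation
sums normalised member expression per set (a flag allows aggregating raw
counts first and renormalising). Duplicate gene ids within a GMT line are
collapsed.

## Importance-matrix analysis

**NMF.** B ≈ WH with non-negative factors, rank k = 2 by default, fit by
seeded multiplicative updates on the Frobenius objective; the objective is
recorded per iteration (it is provably non-increasing, and asserted so in
tests). Initialisation is seeded scaled |N(0,1)| — deterministic given the
seed; sklearn's coordinate-descent NMF serves as an independent
reconstruction-error cross-check in the tests, not as the implementation.
The "discriminative factor" is the W column with the largest two-class
|rank-sum| statistic; per-factor feature contributions are the H row
normalised to sum 1.

**PCA.** Column-mean-centred SVD (sklearn). `pca_ordinate` defaults to
covariance mode (importance entries share a unit: probability mass). The
*pipeline's* heterogeneity analysis, however, standardises columns first
(correlation mode, `pca_scale: true`): once attention concentrates, B's
columns span more than two orders of magnitude, and covariance-mode top axes
are dominated by sample-to-sample competition noise among the few
high-importance columns, hiding coordinated within-class structure on
moderate-importance features — exactly the structure this analysis exists to
reveal. Both modes are one flag apart; loadings are sign-indeterminate and
all test comparisons are up-to-sign.

**Stage association.** Per ordination axis, OLS of the axis scores on
dummy-coded T, N and M (nominal, lowest level = reference, all three factors
jointly in one model), restricted to one class. Factors constant within the
subset are dropped with a warning. Raw two-sided p-values are reported, with
an optional Benjamini–Hochberg column; with a single binary factor the
coefficient p-value reduces exactly to the pooled-variance t-test.

**Baselines.** L2 logistic regression and a linear soft-margin SVM
(sklearn), fit on identically preprocessed features and scored by test-set
F1, tabulated rows = feature space, columns = model.

## Synthetic cohorts

The generator emulates the statistical regime the method targets, not any
particular dataset. Counts are negative-binomial (gamma–Poisson), mean
lib_j · μ_base · exp(effects), variance μ + φμ² with dispersion φ = 0.3;
library multipliers lib_j are log-normal (σ = 0.3) so size-factor
estimation is non-trivial. Defaults: 150 samples per class, d = 500, 10
planted features with natural-log fold change 2 up-regulated in the severe
class (B, y = 0), stage 1–4 assigned with class A skewed low
(0.4/0.3/0.2/0.1) and class B high (reversed). Severity continuum: 10
gradient features shift proportionally to stage — by
effect · (stage−1)/3 — for a random half of class A (the heterogeneous
subgroup) and for every class-B sample, realising the premise that part of
the milder class lies on the same severity continuum as the severe class.
Clinical exports map stage to T1–T4, with N0–N2 noisily monotone in stage
and M1 rare except at stage 4. The gene-set emulator produces signal sets
containing the planted features, null sets, an overlapping pair, and one
set below the size-10 filter.

What the generator does **not** emulate: gene–gene correlation beyond the
planted structure, realistic per-gene baseline/dispersion spectra, batch
effects, or annotation-scale feature counts (tests use d = 500, not
20 000). Passing tests therefore demonstrate that the machinery recovers
planted structure under idealised but statistically honest conditions; they
do not certify performance on real tumour cohorts.

## Pipeline conventions

Importance is always scored on held-out test samples only, and the pipeline
asserts no training sample id reaches the importance matrix. Splits are
stratified by class, seeded; when a patient id column is supplied, every
sample of any patient with more than one sample is removed before splitting.
Each run writes a manifest (config hash, derived seeds, stage log) and is
byte-reproducible for fixed config and seed.

## Numerical choices and degenerate inputs

Softmax uses max-subtraction; tied scores receive equal weight. Batch-norm
uses ε = 1e-5, momentum 0.1, unbiased running variance; training batches of
size 1 are skipped (batch-norm degeneracy). Probabilities are clipped at
1e-12 inside the log-loss. NMF divisions are guarded by 1e-12; PCA requires
n ≥ 3 samples. Size-factor estimation raises if no feature is all-positive;
zero-feature filtering raises on an all-zero matrix; single-class labels
raise before training.

## Known limitations

- Attention concentration varies across training seeds at n ≈ 300; the
  within-class gradient axis in particular is a small-variance signal whose
  recovery strength fluctuates run to run. Larger cohorts stabilise it.
- The two-factor NMF may attach the class contrast to either factor when two
  planted signal populations exist (class features and continuum features);
  the discriminative-factor statistic picks one of them.
- The model is binary by design; multi-class extension would require a
  different head and loss.
- The stage linear models report raw p-values by default, mirroring common
  practice for a handful of coefficients; use the BH column when screening
  many axes.
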