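# deeptriage

Attention-based, interpretable classification of high-dimensional gene
expression, with per-sample, per-feature importance scores.

## The problem

Bulk RNA-seq classifiers for cancer sub-types face a p ≫ n regime (tens of
thousands of genes, hundreds of samples) and are typically interpreted only
at the *class* level: a feature is important for luminal B versus luminal A,
full stop. Clinically, much of the interesting biology lives *within* a
sub-type — for instance, some luminal A tumours sit close to luminal B along
a severity continuum. This package implements an attention architecture that
classifies samples while emitting an **individualised importance score**
for every feature of every sample, and the multivariate machinery (NMF,
PCA biplots, clinical-stage linear models) to mine those scores for
intra-class heterogeneity.

## The model

Let x_j = [x_j1, …, x_jd] be sample j in a d-dimensional non-negative
feature space (genes, or GO/KEGG gene-set aggregates). Each feature i owns a
fixed random embedding vector e_i ∈ R^m (row i of E, entries N(0, 1/m),
m ≪ d), and

1. **embedding** x̂_j⁽ⁱ⁾ = x_ji · e_i  (multiplicative interaction; no
   trained parameters),
2. **self-attention** α_ji = f_α(x̂_j⁽ⁱ⁾) with a shared one-hidden-layer
   tanh scorer — a feature's score depends only on that feature,
3. **normalisation** β_j = softmax(α_j), so β_ji > 0 and Σ_i β_ji = 1,
4. **representation** x̄_j = Σ_i β_ji f_x(x̂_j⁽ⁱ⁾), f_x a single tanh
   layer m → p,
5. **classification** Pr(y_j = 1) = f_y(x̄_j), one hidden layer with batch
   normalisation and ReLU, sigmoid output.

All parameters are learned end-to-end by minimising the binary log-loss
with Adam; dropout (rate 0.5) acts on f_x, f_α and f_y during training.
Because the three sub-networks share weights across features, the parameter
count is independent of d. Stacking the β_j of held-out test samples gives
the importance matrix **B**, which is then factorised (NMF, seeded
multiplicative updates) to find the factor that best separates the classes,
and ordinated (PCA) to expose within-class structure that can be regressed
on clinical T/N/M stage.

The implementation is pure NumPy with hand-derived analytic gradients
(verified against finite differences in the test suite).

## Worked example

Everything is testable without downloads through the built-in synthetic
cohort generator (negative-binomial counts, log-normal library sizes, two
classes with planted discriminative features, and a within-class severity
gradient tied to an ordinal stage):

```bash
deeptriage simulate --seed 3 --out cohort/
cat > run.yaml <<EOF
counts: cohort/counts.tsv
labels: cohort/labels.tsv
clinical: cohort/clinical.tsv
out_dir: results/run
EOF
deeptriage run --config run.yaml --seed 3
```

which prints

```
wrote cohort (300 samples x 500 features) to cohort/
run complete: results/run
```

and leaves in `results/run/`: `importance.tsv` (the 100 × 500 test-set
importance matrix B, every row summing to 1), `predictions.tsv`,
`baselines.tsv` (test-set F1 of L2 logistic regression, linear SVM and the
attention model — 1.0 for all three on this clearly separable cohort),
`factor_contributions.tsv` + `factor_boxplot.png` (the NMF factor separating
the classes and its per-feature contributions), `pca_scores.tsv` /
`pca_loadings.tsv` + `biplot.png`, `stage_association.tsv` (OLS of each PCA
axis on dummy-coded T/N/M among one class), and `manifest.json` (seeds,
config hash, stage log) making the run exactly repeatable — a second
invocation with the same config and seed reproduces `importance.tsv`
byte-for-byte.

The same steps are available as a library:

```python
import deeptriage as dt

cohort = dt.generate_cohort(dt.SyntheticConfig(seed=3))
norm = dt.normalize_counts(cohort.counts, dt.estimate_size_factors(cohort.counts))
train, test = dt.split_cohort(norm.sample_ids, cohort.labels, test_fraction=1/3, seed=4)
model = dt.fit(norm.subset_samples(train), cohort.labels[[norm.sample_ids.index(s) for s in train]])
B = dt.score_importance(model, norm.subset_samples(test))   # rows sum to 1
```

Gene-set (GMT) collections are supported throughout: `deeptriage preprocess
--counts … --gmt sets.gmt` removes sets with fewer than ten measured member
genes and sums normalised member expression into annotation-level features.

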