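# Methods

## Model

A cohort of gene-annotated variant calls is treated as a document
collection: each sample is a document, each gene a term, and the term
frequency tf(g, s) is the number of retained mutations of gene *g* in
sample *s*. Only exonic and intronic variants are retained (they carry an
unambiguous gene label); the location filter can also restrict to either
class alone to study where the classification signal lives.

Six weighting schemes map the count matrix to features:

- **binary** — presence/absence; the baseline that discards multiplicity.
- **cscore** — per-cell sum of per-variant deleteriousness scores
  (CADD-style C-scores, supplied with the input; the package never
  computes them). Inherits count information through the sum.
- **tf-idf** — tf(g,s) · log(N / df(g)), down-weighting genes mutated in
  many samples, df(g) = #{s : tf(g,s) ≥ 1}.
- **tf-rf** — tf(g,s) · rf(g, c(s)) with
  rf(g,c) = log(2 + a / max(1, b)); *a* and *b* count mutated samples
  inside and outside class *c*. Supervised: the same gene weighs more in
  the class where its mutations concentrate. rf ≥ log 2 by construction.
- **bm25-tf-idf / bm25-tf-rf** — as above with the Okapi saturating term
  frequency BM25-tf = (k+1)·tf / (k+tf). Because every sample is
  represented over the same gene feature set, the document-length part of
  the full Okapi formula cancels (L_s = L_ave) and only the smoothing
  parameter *k* survives; the general form is therefore not implemented
  separately. BM25-tf is 0 at tf=0, exactly 1 at tf=1 for every k,
  bounded by k+1: a gene with n mutations is deliberately not n times a
  gene with one.

Parameters that matter: *k* (dimensionless, default 0.8 — the value that
tunes best for this data type; larger k weakens saturation), and the
logarithm base for idf/rf (natural log by default, configurable to 2 or
10; it is a monotone rescaling only and is pinned purely for
reproducibility).

### Supervised weights for unlabeled samples

rf is defined per class, so transforming a sample without a label needs a
policy. Two are implemented:

- `rf_test_policy="max_over_classes"` (library default): each gene is
  scored by its most favourable class. Deployment-safe (no label used),
  but the resulting features are a different quantity from label-resolved
  weights, and mixing label-resolved training rows with max-resolved test
  rows creates a measurable covariate shift.
- `rf_test_policy="true_label"` / `statistics_source="transductive"`: the
  supervised weights are resolved with each sample's class (and, in the
  transductive mode, df/rf are computed on the full corpus before
  splitting). This is the mode the evaluation protocol of record implies,
  and the protocol-level tests use it; it leaks label information into the
  *features* of test samples, which must be stated with any score reported
  under it. The classifier itself still never trains on test rows.

`statistics_source="fit_corpus"` (default) computes df/rf on the 80%
training portion only.

## Evaluation protocol

Stratified 80/20 train/test split; 10-fold stratified cross-validation on
the training portion for hyperparameter tuning (mean CV accuracy, ties
broken by grid order, infeasible grid points recorded and skipped);
testing repeated 10 times by retraining the tuned model on each fold's
training partition and evaluating on the common held-out 20%. Reported
values are mean ± std over the repetitions. An assertion verifies on
every run that no test index appears in any tuning or training index set.

Micro-averaged precision, recall and F-score are mathematically identical
to accuracy for single-label multiclass predictions (and the tests assert
this identity), so macro and class-weighted averages are reported
alongside to expose per-class behaviour. The scalar FPR is the
class-weighted mean of per-class one-vs-rest FP/(FP+TN). ROC-AUC is
one-vs-rest macro over predicted class probabilities; SVM decision scores
are softmax-normalised for this purpose, and the value is reported NaN
with a warning when a class is absent from the test truth.

The feed-forward network is a numpy implementation: `n_layers` hidden
layers whose widths halve from `first_layer_units` (odd widths round
down with a warning), inverted dropout after every hidden layer, softmax
head, categorical cross-entropy, mini-batch Adam (or SGD), a fixed
schedule of 50 epochs with batch size 50 and no early stopping. All
randomness (init, shuffling, dropout masks) flows from one seed, and
dropout is inactive at inference, so prediction — and therefore probing —
is deterministic given the fitted weights.

## One-hot gene probing

Each trained fold network is fed unit vectors e_g (feature value exactly
1.0 at one gene, 0 elsewhere, regardless of the weighting scheme's actual
feature scale — a documented simplification that keeps maps comparable
across schemes). The softmax outputs are per-fold heat maps; the final
genes × classes map is their arithmetic mean. Sorting a class column
descending (ties broken lexicographically by gene symbol) yields the
genes most effective for predicting that class.

## Synthetic cohorts

The generator emulates the structure the schemes assume: per-cell
mutation counts are Poisson with a uniform `background_rate` per gene per
sample, and each class owns a disjoint set of `planted_genes_per_class`
genes whose rate is multiplied by `planted_rate_multiplier` in that
class's samples. Each mutation event draws a location (exonic with
probability 0.15, the minority share typical of whole-genome variant
sets, else intronic) and a gamma(2, 5) score on a CADD-like scale
(mean 10), optionally shifted for planted genes.

Defaults: 2 classes × 100 samples, 200 genes, background rate 0.5,
5 planted genes per class, multiplier 5. The rate gives every sample on
the order of 80 distinct mutated genes — a per-gene mutation density
comparable to dense whole-genome variant cohorts — and puts the planted
signal (in-class Poisson mean 2.5 per planted gene vs 0.5 outside) far
enough from the background that the two classes are genuinely linearly
separable, which is the defining property of the `separable` fixture: a
logistic regression reaches ≈1.0 held-out accuracy on it. The
`imbalanced10` fixture reuses these rates with 10 classes whose sizes
follow a frequency-ranked cancer-cohort profile scaled to ~700 samples.

What the generator does **not** emulate: mutational signatures, gene
length and replication-timing effects on background rates, inter-gene
correlation, hypermutator samples, and genome coordinates. Passing tests
therefore demonstrate correctness of the pipeline and recoverability of
planted class structure, not expected accuracy on real tumor cohorts.

## Numerical and design choices

- Genes never seen mutated in the fit corpus (possible with an external
  vocabulary) have no defined idf; they are assigned weight 0 under all
  idf/rf schemes — a never-mutated gene carries no corpus signal.
- All weighting is computed in double precision with no rounding before
  serialization; representations are zero exactly where counts are zero.
- ANNOVAR multi-gene annotations ("GENE1;GENE2") credit the mutation to
  every listed gene; multi-allelic VCF sites yield one record per ALT
  allele; functional labels other than exonic/intronic (splicing, UTR,
  ncRNA_intronic, ...) map to "other" and are dropped by every location
  filter. These conventions are choices of this package — the counting of
  such records is not standardised.
- Gene symbols are compared case-sensitively after whitespace stripping.
- Whether the 10 test repetitions should also re-tune per fold is
  ambiguous; here tuning happens once on the CV folds and only the
  training subset varies across repetitions.
- "NB" is multinomial naive Bayes (features are non-negative count-derived
  weights); "perceptron" is a single-hidden-layer network, matching a
  tuning space that includes a hidden layer size.
- Test-scale runs use a reduced network (first layer 128 units, 2 layers)
  on 200-gene cohorts; the full-scale configuration of record
  (4 layers, first layer 8192) is expressible with the same `NNSpec` but
  is pointless below thousands of features.

## Known limitations

- The transductive supervised mode leaks class information into test
  features (see above); scores under it measure the representation as
  used in the protocol of record, not deployment performance on unlabeled
  samples.
- The probe's unit-vector input ignores that real bm25-tf-rf features can
  exceed 1; probe probabilities are comparative, not calibrated.
- The numpy network is designed for desk-scale cohorts (hundreds of
  samples, hundreds to thousands of genes), not GPU-scale corpora.
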