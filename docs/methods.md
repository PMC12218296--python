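# Methods

## Problem and data model

The framework classifies small molecules as active or inactive against the
glucocorticoid receptor from their fingerprints. Curation follows the
standard QSAR recipe: only measurements reported with an exact relation
("=") and a present IC50 are kept; exact duplicate (compound, value) pairs
collapse to one row; replicate measurements of a compound are averaged on
the pIC50 scale but the compound is discarded when its replicate pIC50
standard deviation exceeds 2 (the cutoff and the aggregation statistic,
mean or median, are configurable — the filter's published description is
ambiguous, and this is the most common reading). Potency converts as
pIC50 = −log10(IC50 in molar) = 9 − log10(IC50 in nM). Labels: active
above pIC50 6, inactive below 5; the [5, 6] band is "intermediate" and
excluded downstream. The independent test split draws fixed per-class
counts uniformly without replacement under an explicit seed.

A note on bookkeeping: with 1,314 actives / 275 inactives and a 263/55
test split, the training remainder is 1,051/220 by arithmetic; the
published description of the same data states 1,054/214. The package
always reports its own arithmetic and uses 1,054/214 only where those
numbers serve as given inputs (the balancer size table).

## Feature views and fusion

Five fingerprint views per compound — AP2D (780), CDKExt (1024),
Klekota-Roth (4857), Morgan (2048), RDKit (2048) — are concatenated in
that fixed order into a 10,757-column matrix, with the column range of
each view recorded so slicing recovers the inputs exactly. Fingerprint
computation sits behind a provider interface: file-backed (precomputed
CSVs), RDKit-backed (Morgan and RDKit views; SMILES canonicalized,
largest fragment kept), or synthetic (seeded hash-derived bits). The bit
definitions of AP2D/CDKExt/KR are deliberately out of scope — the package
consumes those views, it does not re-implement them.

## Balancing

`target = round(n_min + p·(n_maj − n_min))` interpolates the per-class
size between the minority count (p = 0, pure undersampling) and the
majority count (p = 1, pure oversampling); outputs are exactly 1:1 at
every p. SMOTE synthesizes `target − n_min` minority rows as
`x_i + λ·(x_nn − x_i)` with λ ~ U(0,1) and `x_nn` one of the k = 5 nearest
minority neighbours (Euclidean); the majority class is undersampled
uniformly without replacement. Synthetic values stay continuous in [0, 1]
(standard SMOTE output; they are not re-binarized). Two cross-validation
modes exist because the published protocol does not say when balancing
happened: **safe** (default) balances inside each training fold only, so
synthetic rows can never reach a validation fold, and **paper** balances
once before folding; reports name the mode.

## The BGATT network

The published architecture gives the recurrence and attention equations
but not the tokenization of a 10,757-D vector into a sequence. Design
choice: one token per descriptor view (a length-5 sequence), each view
linearly projected to d_model = 512; fixed-size chunk tokenization is
available as an option (`chunk_size`). The attention equation as printed
omits the multiplication by V; the standard scaled dot-product form
`softmax(QKᵀ/√d)·V` is used. The candidate-state term is read as
`r ⊙ (W_c h_{t−1})` (reset gate applied to the transformed previous
state). Hidden states start at zero; recurrent weights get an orthogonal
seeded initialization (QR of a Gaussian), input maps Glorot-uniform.

The embedding is the attention output mean-pooled over tokens: width
2·d_h, i.e. 4000 at the default d_h = 2000. A sigmoid head trains the
whole stack on binary cross-entropy. The training protocol is this
package's own (none is published): Adam at learning rate 1e-3, 50 epochs,
batch 32, early stopping after 10 epochs without training-loss
improvement beyond 1e-5. Gradients are hand-derived NumPy; the test suite
checks them against central finite differences and the layer equations
against element-by-element loop oracles at 1e-10.

Numerical notes: the logistic sigmoid comes from `scipy.special.expit`
(stable in both tails); softmax subtracts the row maximum; probabilities
are clipped at 1e-12 inside the loss only; a non-finite loss aborts
training with diagnostics rather than continuing.

## Reduction and classification

PCA is fitted on training rows only; k is the smallest component count
whose cumulative explained-variance ratio reaches the threshold (default
0.95; a threshold of 1.0 keeps all min(n−1, width) components). In the
composed pipeline PCA applies exactly when the embedder is on — the
reduction targets the embedding space; ablation strategies without the
embedder send fused features to the classifier directly, matching how the
published baseline and balancing-only rows behave. This is forceable
either way (`use_pca`).

The final classifier is extremely randomized trees. The eleven baselines
share one protocol: grid search by stratified 10-fold CV on identical
fold assignments (shared seed), selection by AUPR — the headline metric;
the published grids are not available, so the defaults declared in
`DEFAULT_GRIDS` are used and fully overridable. PLS acts as a classifier
via regression on {0, 1} clipped to [0, 1] and thresholded at 0.5
(PLS-DA). A single-point grid skips the search.

## Metrics and the positive class

SN, SP, BACC = (SN+SP)/2 (exact identity, asserted), F1, MCC (0 when any
marginal is 0), AUC by the trapezoidal rule, AUPR by step-wise
precision-recall summation (average precision). Threshold metrics default
to the **minority (inactive) class as positive**: the published
independent-test row (SN 0.964, SP 0.951, MCC 0.853, F1 0.876) is only
consistent with 55 positives and 263 negatives. The choice is
configurable and every report names its positive class. Cross-validated
metrics are macro-averaged over folds, not pooled.

`recover_cm_from_rates` inverts printed (SN, SP) pairs to integer
confusion-matrix cells by exhaustive search over tp ∈ [0, n_pos] and
tn ∈ [0, n_neg]; a unique match grounds the regression tests against the
published tables, no match flags a table inconsistency.

## Synthetic fixture

The generator draws the five views as Bernoulli bit matrices: 80
class-discriminative columns per view (active density 0.5, inactive 0.1),
background density 0.2 everywhere else, then a 0.1 independent bit-flip
on every bit; 500 actives / 100 inactives mirror the real data's ~1:5
imbalance. The signal strength was set by a design constraint discovered
while building the generator: with a much weaker planted signal
(e.g. 0.45 vs 0.15 on 50 bits) tree ensembles still *rank* the classes
well in 10,757 dimensions but cannot *threshold* them — hard labels
collapse to the majority for balanced and unbalanced training alike, so
the fixture would exercise nothing. At the chosen strength the imbalanced
baseline still visibly under-recalls the minority class while the
balanced pipeline recovers it, reproducing the qualitative ordering of
the published ablation across seeds.

What passing on this fixture does **not** show: fingerprint bits here are
i.i.d. within a class, while real fingerprints are sparse, correlated and
structured by chemistry; absolute metric values on the fixture (often
1.0) say nothing about performance on assay data. The fixture validates
mechanics — leakage safety, balancing arithmetic, that the embedding
preserves and concentrates class signal — not chemistry. The synthetic
SMILES strings are short linear heteroatom chains: parseable, not
drug-like.

## Problem sizes used in checks

The end-to-end checks run the default 600-compound fixture with the
network at d_model = 64, d_h = 64, 30 epochs — sizes chosen so a full
ablation completes in well under a minute on one CPU while leaving the
architecture (5-token BiGRU, attention, PCA, ET) identical to the
full-scale configuration. The paper-scale defaults (d_h = 2000,
embedding 4000) remain the constructor defaults.

## Known limitations

* The BGATT layer stack beyond the embedding width is unverifiable from
  the published description; layer counts and widths other than 4000 are
  this package's choices.
* Grid-search grids and the selection metric are declared defaults, not
  published values.
* The percent-improvement sentences in the published ablation discussion
  are arithmetically inconsistent with its tables and are not recomputed.
* Training the NumPy network at full scale (d_h = 2000 on ~1,700
  compounds) is possible but slow; the implementation is single-threaded
  BLAS-bound and has no GPU path.
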