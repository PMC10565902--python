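# Methods

`a2isite` predicts adenosine-to-inosine (A-to-I) RNA editing sites from
fixed-length RNA sequence windows centred on a candidate adenosine. This
note documents the model, its parameters and defaults, the synthetic
data the package is validated on, and the numerical choices made where
the design was genuinely open.

## Problem setting

A-to-I editing, catalysed by ADAR enzymes acting on double-stranded RNA,
is the most prevalent RNA editing event; an edited adenosine is read as
guanosine by the cellular machinery. The prediction task is binary
classification of a window (51 nt for human and fly conventions, 41 nt
for mouse, always with the candidate A at the centre position
(L + 1) / 2) as editing site or non-site. Benchmark collections for this
task are approximately balanced but balance is never assumed; class
counts are reported, not enforced.

## Sequence descriptors

Eleven encoders map a window of length L to a fixed-dimension numeric
vector. Let f(d) denote the adjacent-dinucleotide frequency
count(d)/(L−1), with dinucleotides ordered lexicographically over
(A, C, G, U).

| Encoder | Dimension | Content |
|---|---|---|
| Kmer(k) | 4^k | k-mer frequencies |
| CKSNAP(g_max) | 16 (g_max+1) | pair frequencies at gaps 0..g_max |
| ASDC | 16 | pair frequencies pooled over all skip distances |
| ENAC(w) | 4 (L−w+1) | per-window base fractions, 5'→3' |
| NCP | 3 L | chemical-property bits per base |
| DPCP | 96 | f(d) × six step parameters |
| DPCP2 | 4 (L−1) | per-position step parameters (rise, roll, shift, slide) |
| PseDNC(λ, w) | 16 + λ | pair frequencies + sequence-order factors |
| Binary | 4 L | per-base one-hot |
| DBE | 4 (L−1) | 2-bit base codes per pair (A=00, U=01, C=10, G=11) |
| PS2 | 16 (L−1) | per-pair one-hot |

Choices worth recording:

- **Kmer denominator.** The literal composition definition divides
  counts by the sequence length L, under which k-mer vectors do not sum
  to one for k > 1. The default mode `windows` divides by the number of
  k-mer windows L − k + 1 (the convention of the standard
  descriptor-extraction toolkits), which restores
  the sum-to-one invariant; the literal `length` mode is kept available.
- **ASDC gap semantics.** "g-gap" pairs positions (p, p + g), so g = 1
  is the ordinary adjacent dinucleotide; gaps run 1..L−1 and the grand
  total normalizes the vector to one.
- **CKSNAP blocks.** Default g_max = 2 gives the 48-dimensional vector
  (16 × 3); each gap block is normalized by its own pair count
  L − g − 1 and sums to one.
- **PseDNC.** λ = 2 by default; the weight w is only constrained to
  [0, 1] by the descriptor family, and the package uses the
  literature-conventional default w = 0.1. The correlation factor θ_j
  averages, over positions, the mean squared difference of the six
  standardized step parameters between pairs j apart. At w = 0 the
  vector reduces exactly to the adjacent-pair frequencies.
- **Physicochemical table.** The bundled 16 × 6 table
  (`data/rna_dinucleotide_steps.tsv`) carries A-form RNA base-step
  parameters — rise, roll, shift, slide (Å-scale translations), tilt,
  twist (degrees) — from the crystallographic parameter sets used by
  the pseudo-composition descriptor lineage. PseDNC standardizes each
  property to mean 0 / unit sd over the 16 dinucleotides before use;
  DPCP/DPCP2 use raw values by default (standardization available via
  `PhysicochemicalTable.standardize()`).
- **DBE code.** The 2-bit base code A=00, U=01, C=10, G=11 reproduces
  the worked examples AA→0000, AU→0001, AC→0010, GG→1111.
- **Species encoder presets.** Hs: NCP + Binary + DBE + PS2;
  Mm: NCP + ENAC(2) + Binary + DBE + DPCP2;
  Dm: CKSNAP(2) + Kmer(3) + ASDC + PseDNC(2, 0.1) + DPCP. Any explicit
  encoder list can replace a preset.

## Stacked ensembles

Base classifiers come from six classical algorithms: extra trees (ET),
random forest (RF), gradient-boosted decision trees (the `CatBoost`
tag), logistic regression (LR), ridge classification (Ridge) and linear
discriminant analysis (LDA). The gradient-boosting backend is
scikit-learn's `GradientBoostingClassifier`, which provides the
impurity-based feature importances the selection strategies rely on.
Hyperparameters are library defaults with a fixed seed; everything is
overridable per learner.

Meta-features are **out-of-fold** positive-class probabilities: a
seeded stratified K-fold split (default K = 5) trains every base
learner K times and scores only held-out rows, so no row is scored by a
model that saw it — the standard guard against stacking leakage. The
meta-classifier is fit on these probabilities; base learners are then
refit on all rows for deployment. Ridge has no probability output; its
decision function is passed through the logistic function so all base
learners feed the meta-learner on a common [0, 1] scale.

Species presets: Hs uses Ensemble3 (base ET + RF, meta ET); Mm uses
Ensemble1 (base CatBoost + ET, meta ET); Dm uses Ensemble5, six base
learners balancing three tree-based and three linear models
({ET, CatBoost, RF} + {LR, Ridge, LDA}) with an LR meta-learner. The
exact Ensemble5 membership and meta-learner are a documented default
(the balancing principle constrains but does not fix them) and are
fully configurable.

Classification threshold defaults to 0.5 with probability ≥ threshold
counted positive.

## Incremental feature selection

Both strategies rank descriptors by a classifier's feature importance
(impurity importances for tree learners; absolute coefficients on
per-column standardized descriptors for linear learners, for which a
constant column gets importance exactly 0) and scan prefixes of the
ranking with repeated stratified CV, recording mean MCC and AUROC per
prefix size k. Optimal k maximizes mean MCC; ties break by mean AUROC,
then by smallest k (parsimony).

- **Strategy 1** scans per base classifier, evaluating that single
  classifier on each prefix, and fits the final stack on the union of
  the per-classifier optimal subsets.
- **Strategy 2** uses one global ranking — by default from the base
  classifier with the best standalone CV MCC — evaluates the full stack
  on each prefix, and fits the final stack on the optimal prefix.

Species presets: Strategy 2 for Hs, Strategy 1 for Mm and Dm.

The full scan visits every k in 1..m, which is quadratic-in-m expensive
under repeated CV; the default grid is therefore complete for m ≤ 50
and ~50 log-spaced values (always including 1 and m) above that. Any
explicit grid can be supplied.

## Evaluation

Metrics: Recall, Specificity, Accuracy, Precision, F1 and the Matthews
correlation coefficient from the confusion table, plus AUROC as the
Mann–Whitney rank statistic (ties counted one half), which is exactly
pairwise concordance and invariant under monotone score transforms. Any
ratio with a zero denominator is reported as NaN with a warning, never
silently as 0.

Protocols: repeated stratified k-fold CV (default 10 × 10; both
fold-mean ± sd and pooled metrics are reported, fold means as the
headline), leave-one-out (n fits pooled into a single confusion table —
the only aggregation under which MCC is defined at fold size 1), and a
stratified 70/30 hold-out. All splits are seeded; identical inputs and
seeds give bit-identical results.

## Synthetic data

The generator emulates the *structure* of editing-site benchmarks, not
any particular collection: fixed-length windows with a centre adenosine
in both classes (negatives are also candidate adenosine sites),
positives drawn from a background composition mixed per position with
an enrichment distribution, negatives from the background alone. The
default signal mirrors the qualitative neighbour preference of
deaminated sites — a strong G preference immediately 3' of the centre,
a U/C preference 5', decaying enrichment out to ±5 — with an effect
size in [0, 1] interpolating from no signal to full enrichment. At full
effect the classes are strongly separated (Bayes AUROC ≈ 0.97 by direct
likelihood-ratio simulation), comparable to the stronger real
benchmarks; at effect 0 the classes are exchangeable, which calibrates
the null behaviour of the whole pipeline. The background is uniform by
default with a G/C-rich named option.

What the generator does not emulate: double-stranded RNA structure,
editing levels, genomic context or linkage between positions
(positions are drawn independently). Passing tests therefore
demonstrate that the machinery recovers planted positional signal and
stays calibrated under the null — not that any particular real-data
accuracy will be achieved.

`planted_feature_matrix` is the descriptor-level analogue: balanced
classes, informative columns whose class means differ by a stated
standardized effect, independent standard-normal noise columns, and
column names that flag the ground truth for recovery assertions.

## Problem sizes used in the checks

The end-to-end checks run at sizes chosen for a single CPU: null
calibration uses 10 seeds × 100 windows (51 nt, NCP + Kmer(3), 10-fold
CV); signal recovery uses 200 windows with the full Hs preset; the
selection-recovery checks use 3 informative + 27 noise columns at
n = 400 over 10 seeds with an 11-point prefix grid. The acceptance
script (`scripts/acceptance.py`) re-runs the same computations from
scratch at the same sizes.

## Known limitations

- The bundled step-parameter values are the package's own assembly of
  published A-RNA parameters; other tables in circulation differ in
  detail, which shifts DPCP/DPCP2/PseDNC values but none of the
  analytic invariants.
- Feature "importance" for linear models (|standardized coefficient|)
  is one defensible convention among several.
- LOO and Strategy 2 at large m are computationally heavy by design;
  the package scales them by grid striding, not by changing the
  procedures.
- Models are species-specific; nothing transfers a fitted stack across
  window lengths or species.
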