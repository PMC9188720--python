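# Methods

## Problem formulation

GRN inference is cast as one binary classification problem per
transcription factor.  Given a genes × cells expression matrix (values are
used as supplied — counts, TPM or log-scale alike; the package applies no
normalisation) and a gold-standard directed edge set, the candidates for TF
*t* are all genes of the gold network's universe except *t* itself (*t* is
retained as its own candidate only when the gold standard contains a
self-edge).  A candidate's feature vector is its raw expression profile
across all cells — the TF's identity is carried by the problem, not
concatenated into the features — and its ±1 label is gold-edge membership.
Non-positives are treated as true negatives; the positive–unlabeled nature
of curated networks is a known approximation of this framing and is not
modelled.

**Zero-positive rule.**  A TF with no positive in its candidate set admits
no training signal: every candidate is recorded with score exactly 0.0 and
its (negative) label, with fold id −1.  The same rule is extended to the
fold level: if a CV training fold contains a single class (e.g. under LOOCV
when a TF's only positive is held out), its test samples receive the
constant score of that class (0.0 for all-negative folds, 1.0 for the
degenerate all-positive case) rather than a trained model's output.

## Cross-validation and score pooling

Splits are produced per TF problem from `(labels, scheme, seed)` only, so
every classifier compared under one scheme sees byte-identical folds.
k-fold is stratified by default (a mandatory seed fixes the shuffle);
stratification falls back to plain k-fold when no class has k members.
Test folds partition the candidate set, so each (TF, candidate) pair is
scored exactly once, by a model that never saw its label — the held-out
contract checked by the instrumented integrity tests.

Scores are pooled across TFs into a single ranked edge list and evaluated
by one pooled ROC/AUC; a per-TF macro-average AUC (over TFs with ≥ 1
positive) is available as a secondary summary via `--per-tf`, covering the
alternative convention of averaging per-TF curves.

## Classifiers

Model fitting is delegated to scikit-learn; the package's own contributions
are the problem construction, the scoring contract, and the directly
implemented kernel (linear, polynomial `((x·y)+1)^d`, RBF
`exp(−γ‖x−y‖²)`) and Gini-impurity (`1 − Σ p_i²`) utilities.

All nine methods emit positive-class probabilities in [0, 1]:

- SVMs output margins, not probabilities, so a logistic curve is fitted to
  the training-fold decision values (Platt-style, strongly unregularised,
  coefficient constrained non-negative so the map is monotone in the
  margin).  This preserves the margin ranking while making scores poolable
  across TFs.
- KNN's score is the fraction of positive neighbours; its neighbourhood
  shrinks to the training-fold size when a fold has fewer than K samples.
- Tree ensembles, naive Bayes, logistic regression and CART use their
  native `predict_proba`.

Defaults (all overridable): C = 1, degree d = 3, γ = "scale"
(1/(p·var)), 100 trees for RF/GBDT, K = 5 neighbours, library-default tree
depths.  Hyperparameters are deliberately conventional; no tuning or
search is performed.

Features are z-scored per cell inside each fitted pipeline.  Placing the
scaler inside the model (rather than in the orchestration layer) guarantees
by construction that standardisation statistics come from the training
fold only; constant cells standardise to zero.  Scale-sensitive methods
(SVM, KNN, LR) need this; tree methods are unaffected.

## GENIE3-style baseline

For each target gene a random-forest regression (100 trees, √p feature
subsampling) predicts its profile from the candidate regulators (excluding
itself); an edge's score is the regulator's total impurity-reduction
importance, normalised to sum to 1 per target so targets contribute
comparably to the pooled ranking.  Constant targets receive all-zero
incoming scores.  Cells are sorted into a canonical order before fitting so
that scores are invariant to the input's column order (bootstrap resampling
otherwise depends on row order); results remain seed-deterministic.  The
baseline is evaluated on exactly the (TF, candidate) pairs the supervised
pipeline scores, with candidate regulators restricted to the gold TF set
for comparability.  No numerical agreement with any published GENIE3
implementation is claimed.

## Evaluation

AUC is computed by the rank-sum (Mann–Whitney) identity with average ranks,
so tied scores count exactly ½ — numerically identical to the brute-force
pair count, and to the trapezoidal area under the ROC curve.  The ROC curve
itself is the standard descending threshold sweep with one vertex per
distinct score.  The rank table assigns rank 1 to the best AUC per
(dataset, scheme) combination; tied AUCs share their average rank (ranking
is reported at full precision internally and rounded only for display).
The per-method summary is the arithmetic mean rank across combinations.

## Synthetic data generator

The generator emulates the *shape* of small curated single-cell
benchmarks: ~100 genes of which 10 are TFs, 400 cells (the real datasets
this mirrors span roughly 300–800 cells), a sparse directed network
(density 0.15 → ≈ 13–14 targets per TF), and zero-inflated non-negative
expression.  Per cell, on the natural-log scale:

- TF log-levels are i.i.d. N(1, 0.5²) (log-normal profiles);
- each (TF, target) edge is an independent Bernoulli(density) draw; each
  TF carries one activation/repression sign, ±1 equiprobable.  The sign is
  per-regulator, not per-edge: a TF acting consistently is the standard
  simplification, and a per-edge sign would make each TF's positive class
  symmetric-bimodal along its response direction — a structure no linear
  ranker could separate, which would say nothing about the pipeline;
- a regulated target's log-level is 1 + strength · Σ_r s_r (h(x_r) − ½)
  with Hill response h(x) = x²/(K² + x²), K the regulator's median level
  (a linear ramp x/2K, clipped, is config-selectable); unregulated targets
  are independent log-normals;
- N(0, 0.3²) log-scale noise is added, and each matrix entry is zeroed
  independently with probability 0.3 (uniform technical dropout).

Defaults: 10 TFs, 90 targets, 400 cells, density 0.15, Hill effect,
strength 2, noise 0.3, dropout 0.3.  What the generator does **not**
emulate: negative-binomial count noise with per-gene dispersion,
expression-dependent dropout, cell-type mixtures, pseudotime dynamics, and
indirect (TF → TF → target) regulation.  Passing tests on this generator
therefore demonstrate pipeline correctness and calibration — held-out
integrity, a signal the classifiers can recover, a flat null — not
performance on real single-cell data, where dropout structure and network
incompleteness are harsher.

`shuffle_labels` provides the null control: each TF keeps its out-degree
but its targets are redrawn uniformly (no self-edges), so pooled AUC on
the shuffled gold standard should be ≈ 0.5.

## Numerical and design choices

- Scores are written to 6 decimal places; output rows sort by score
  descending with (tf, target) lexicographic tie-break, so files are
  byte-reproducible.
- Expression files with missing entries are rejected, not imputed; id
  matching is exact and case-sensitive.
- Determinism: single-process; every stochastic component (simulation,
  fold shuffling, RF/GBDT) is seeded, and re-runs are byte-identical.
- Problem sizes in the test-suite's end-to-end checks use the generator
  defaults (10 × 90 × 400); unit tests use smaller instances (3–6 TFs,
  10–30 targets, ≤ 200 cells) chosen to exercise the same code paths.

## Known limitations

- Treating unlabeled pairs as negatives biases scores downward for true
  but uncatalogued regulations.
- Platt calibration on separable training folds saturates near 0/1; the
  ranking is unaffected, but the probabilities are not calibrated in the
  frequentist sense.
- The nine classifiers are compared under shared folds but identical
  default hyperparameters; conclusions about method ranking on real data
  would require per-dataset tuning.
- The default synthetic instance is deliberately well-posed and is close
  to saturation (AUC ≈ 1) for the strongest methods; it is a correctness
  floor, not a difficulty benchmark.
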