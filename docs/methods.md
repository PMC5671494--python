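# Methods

## Problem and model

The package addresses binary classification of short peptides (5–30
residues) by whether they induce an IL-17 cytokine response. The only
inputs are amino acid sequences; the hypothesis exploited throughout is
that inducing and non-inducing epitopes differ in residue and dipeptide
composition (Leu-led dipeptides and Leu/Ser/Arg/Asn/Phe marking inducers;
Ala/Asp/Gly/Pro and Pro/Gly-led dipeptides marking non-inducers).

Three feature maps are provided, all on the percent scale of their
defining equations (scaling to [0,1] is available but off by default,
since the classifiers are trained on the percent scale directly):

* **AAC** — 20 residue percentages. Invariant to residue order.
* **DPC** — 400 overlapping-dipeptide percentages; a peptide of length L
  contributes L−1 pairs. Captures local arrangement, hence strictly more
  information than AAC.
* **AAP** — DPC reweighted by a dipeptide propensity learned from the
  training corpus: `w(d) = ln(f⁺(d)/f⁻(d))`, where `f±` are
  pseudocount-smoothed relative frequencies (default pseudocount 1, i.e.
  add-one smoothing; it both prevents log-of-zero and shrinks weights of
  rare pairs), rescaled by `max|w|` so all weights lie in [−1, 1]. The
  log-ratio-times-frequency construction follows the propensity-scale
  design used by earlier composition-based epitope predictors; natural
  log and the [−1,1] normalization are this package's fixed convention and
  are recorded in every model file.

**Classifiers.** The SVM is scikit-learn's SMO-based `SVC`. Kernel
conventions are fixed as: linear `x·y`; polynomial `(x·y + 1)^d` (coef0 =
1, no gamma scaling, so only the degree is a free parameter); RBF
`exp(−g‖x−y‖²)`. The cost factor `j` multiplies the penalty of
positive-class training errors (`C⁺ = j·C` via per-class weights), the
standard device for class imbalance. Decision scores are raw margin
values, deliberately unsquashed: operating thresholds live on that scale
and may be negative. The random forest uses bootstrap trees with `mtry`
features per split (default ⌊√dim⌋, conventional for classification
forests; `ntree` default 500); its score is the fraction of trees voting
positive, computed from per-tree hard votes rather than averaged leaf
probabilities so the score is exactly the vote fraction.

**Thresholding.** A peptide is called an inducer iff score ≥ threshold
(inclusive; exact equality has measure zero for real-valued scores).
Default threshold 0.5 for both families — on the raw margin scale for the
SVM and the vote-fraction scale for the forest.

## Evaluation

ACC, SEN, SPC are percent ratios of confusion counts; MCC uses the
product-denominator form with the convention MCC = 0 when any denominator
factor is zero; SEN/SPC are flagged `None` when a class is absent from the
evaluated set. AUC is computed from midranks (Mann–Whitney with ties
counted ½), which equals the trapezoidal area under the ROC curve; ROC
points come from `sklearn.metrics.roc_curve`.

Cross-validation is stratified: each class is shuffled with the fold seed
and dealt round-robin, so per-class fold sizes differ by at most one.
Held-out scores are pooled across the k folds and metrics computed once on
the pool (rather than averaging per-fold metrics — with pooled raw SVM
scores, per-fold score scales are commensurate enough in practice, and
this convention makes every peptide count exactly once). The operating
point reported is the MCC-maximizing threshold of a sweep over all
midpoints between distinct pooled scores, ties broken toward higher
specificity and then toward the higher threshold. When AAP features are
used, the propensity weights are retrained inside each fold on the
training folds only; the leak of fitting them once on the full dataset
measurably changes pooled scores (a test asserts this), and the leak-free
path is the only one exposed.

The 80/20 train/validation split is stratified per class with
round-half-away-from-zero rounding of the train count. This convention is
fixed and logged; split counts reported elsewhere that imply a slightly
different rounding are not treated as reproducible targets.

## Application modes

* **Peptide prediction** enforces the 5–30 length range per record,
  reporting a per-record error while processing the remainder.
* **Protein scanning** scores every window (step 1, default window 15) and
  reports all windows with labels; merging of overlapping positive windows
  is available but off by default, since per-window reporting is the
  primary output.
* **Metagenomic-read scanning** segments each translated read at any
  character outside the 20-letter alphabet (stops, X, etc.), scans
  segments at least one window long, and exports positive windows as FASTA
  for external similarity search. Whole reads, not inferred ORFs, are the
  unit — segmentation at invalid characters is the recorded choice.
* **Substitution design** produces a dense L×20 matrix (canonical residue
  order); cells of the original residues hold the parent score, so there
  are exactly L×19 true variants. Each variant is scored independently by
  the frozen model.
* **Epitope mapping** reports all exact occurrences, including overlapping
  ones. Similarity mapping is an in-package affine-gap Smith–Waterman
  (Gotoh recursion): a gap run of length k costs `open + extend·(k−1)`,
  defaults BLOSUM62 / 10 / 0.5 — the common protein local-alignment
  defaults, configurable per run. Traceback starts at the highest-scoring
  cell with smallest (i, j) and prefers diagonal > up > left on ties; a
  maximal score of 0 is reported as no hit. Identity is computed over
  aligned (ungapped) columns.

## Composition statistics

Per-feature class comparison uses Welch's unequal-variance t-test on
per-peptide percent compositions (the only reading under which a t-test
applies; pooled counts would demand a different test). No multiple-testing
correction by default — a Bonferroni flag exists — and a permutation test
in the suite documents the consequence: at α = 0.01 over 400 dipeptides,
about 4 false positives are expected under the null. Terminal analysis
compares residue frequencies at positions N1..N5 and C5..C1 with a
two-proportion z-test (the test behind the tabular two-sample-logo
output; named in the output header). Peptides shorter than 10 residues
are excluded there, since overlapping termini would double-count
residues.

## Synthetic data

The generator emulates the statistical structure of a curated epitope
corpus without any database access. Sequences are drawn from class-specific
first-order Markov chains — not i.i.d. residues — so dipeptide-level
signal exists beyond marginal composition and DPC can genuinely beat AAC,
mirroring the qualitative ordering expected of these features. Defaults:
300 positives / 800 negatives (roughly the 1:2.7 class imbalance of real
IL-17 epitope corpora), lengths uniform on 5–30, unique within and across
classes, fully seeded.

Emission distributions add boosts to the favored residues (positives:
L +0.16, S +0.10, R +0.08, N +0.06, F +0.06 over the uniform 0.05;
negatives: A +0.13, G +0.10, P +0.10, D +0.08), giving the favored
residues roughly 2.5–3× enrichment — comparable to the Leu enrichment
reported for real inducing epitopes. Transition rows add +0.15 to the ten
planted positive dipeptides (LL, SL, LK, IL, LI, NL, LR, FK, SF, LE) and
negative dipeptides (PG, GA, AA, GP, PA, PP, AG, GD, PE, AP). These
magnitudes realize a strong planted signal: the default corpus supports
pooled 10-fold CV MCC around 0.9 for the dipeptide SVM. `signal_strength`
interpolates linearly between the uniform chain (0: classes identical)
and the fully biased chain (1, the default). With `terminal_motif` on
(default), the first two residues of positives are drawn from a
Leu-boosted start distribution, planting the N-terminal Leu conservation
that the terminal analysis should recover.

What the generator does **not** emulate: protein-level context, assay
metadata (HLA alleles), homologous redundancy between peptides, and the
heavy-tailed length and composition quirks of real database exports.
Passing tests on synthetic corpora therefore demonstrate correctness of
the machinery and recoverability of planted signal — not field performance
on real epitope data, which depends on the corpus the user supplies.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest sizes chosen as the
package's own trade-off between statistical resolution and turnaround:
the headline recovery checks run on the default 300/800 corpus with
10-fold CV; the signal-strength monotonicity sweep uses 120/320 corpora
with 5-fold CV over 5 seeds; the permutation-null AUC check uses 100/250
corpora over 25 shuffles; the random-peptide negative control scores the
full 10×1,000 15-mers at the stringent raw-score threshold 1.0.

Model files are a single joblib archive (metadata dict with a format
version, the fitted estimator, the AAP weight table, scaler state); the
loader rejects unknown format versions and AAP models missing their
weights, and round-trips preserve scores bit-for-bit. Degenerate inputs
fail loudly and early: empty classes, peptides below the feature map's
minimum length, mtry above the feature dimension, both-zero-variance
t-test samples, gap penalties ≤ 0.

## Known limitations

* SVM decision values depend on the solver's convergence; cross-seed
  reproducibility of CV reports relies on the fixed fold seed, not on
  solver internals.
* The AAP propensity convention (natural log, [−1,1] rescale, pseudocount
  1) is one of several in the literature; models record it, but weights
  are not interchangeable across conventions.
* The forest's vote-fraction score is a step function in ntree; small
  ensembles give coarse thresholds.
* Smith–Waterman is quadratic per pair and intended for epitope-scale
  queries, not genome-scale search.
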