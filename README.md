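# il17pred

Sequence-based machine-learning prediction of IL-17-inducing peptides.

IL-17 cytokines drive pro-inflammatory responses at epithelial and mucosal
barriers, and specific microbial peptide epitopes can trigger their
induction — a mechanism implicated in periodontitis, candidiasis,
autoimmune myocarditis and other inflammatory conditions. `il17pred` is a
library (with a thin CLI) for immunoinformaticians who want to classify
peptides of 5–30 residues as IL-17 inducers or non-inducers from sequence
composition alone, and to apply that classifier to proteins, proteomes and
metagenomes.

## The model

A peptide `s` of length `L` is represented by one of three fixed-length
composition vectors:

* **AAC** (length 20): `AAC(i) = count(aa_i) / L × 100`
* **DPC** (length 400): `DPC(i) = count(dipeptide_i) / (L − 1) × 100`,
  counting the `L − 1` overlapping adjacent pairs
* **AAP** (length 400): DPC weighted per dipeptide by a propensity learned
  from the labeled corpus, `w(d) = ln(f⁺(d)/f⁻(d))` with add-one smoothing,
  rescaled to `[−1, 1]`; the feature is `(DPC_d / 100) · w(d)`

These feed a soft-margin SVM (linear / polynomial `(x·y + 1)^d` / RBF
`exp(−g‖x−y‖²)` kernels, with a cost factor `j` multiplying the penalty of
positive-class training errors) or a random forest (`ntree` trees, `mtry`
features per split, score = fraction of trees voting positive). A peptide
scoring at or above the decision threshold (default 0.5) is called an
inducer. Models are evaluated by stratified 10-fold cross-validation with
held-out scores pooled across folds before computing ACC/SEN/SPC/MCC and
the Mann–Whitney AUC; any learned feature weighting (AAP) is retrained
inside each fold so nothing leaks from the held-out data.

Around the classifier sit the application modes: sliding-window protein
scanning, translated metagenomic-read scanning (with segmentation at stops
and ambiguity codes and FASTA export of positive windows for BLASTP),
exhaustive single-residue substitution design, exact epitope-occurrence
mapping, Smith–Waterman similarity mapping (BLOSUM62, affine gaps), and
class-composition statistics (Welch's t-test per residue/dipeptide,
two-proportion z-tests at the terminal positions).

Real training corpora come from epitope databases and are supplied by the
user (FASTA or labeled TSV); the package curates them (5–30 length filter,
within-class deduplication, removal of negatives that exactly match a
positive) and splits them 80/20. A seeded generator produces synthetic
corpora with the same statistical structure — Markov-chain peptides with
Leu/Ser/Arg/Asn/Phe-enriched positives and Ala/Asp/Gly/Pro-enriched
negatives — so the whole pipeline is testable without any database access.

## Worked example

```python
from il17pred import (GeneratorConfig, Peptide, SVMConfig,
                      generate_corpus, pep_pred, train_svm)

corpus = generate_corpus(GeneratorConfig(n_pos=150, n_neg=400, seed=1))
model = train_svm(corpus, "DPC", SVMConfig(kernel="polynomial", d=2))

queries = [Peptide("leucine_rich", "LLKLLSLNLRFKSFM"),
           Peptide("proline_rich", "PPGAPGAPPGGDPEA"),
           Peptide("mixed",        "AKLSGDWPNRAQTVE")]
for row in pep_pred(model, queries):
    print(f"{row['id']:>14}  score={row['score']:+.3f}  {row['label']}")
```

prints

```
  leucine_rich  score=+3.252  inducer
  proline_rich  score=-3.897  non-inducer
         mixed  score=-0.295  non-inducer
```

The score is the raw SVM margin: the Leu-rich peptide sits far on the
inducer side of the decision boundary, the Pro/Gly-rich peptide far on the
other, and the mixed peptide falls just below the 0.5 default threshold.
The `examples/` directory has one short script per capability
(cross-validation, protein/metagenome scanning, substitution design,
epitope mapping, composition statistics); each prints its results with a
note on what they mean. The same workflows are available from the shell via
the `il17pred` command (`train`, `cv`, `predict`, `scan`, `metagscan`,
`design`, `map`, `simsearch`, `compare`, `simulate`).

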