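"""Compare feature representations by 10-fold cross-validation.

Reproduces the model-selection logic on synthetic data: amino acid
composition (20 features) vs dipeptide composition (400 features) with
the same polynomial-kernel SVM. Held-out scores are pooled over the 10
folds and ACC/MCC/AUC computed once on the pool; the operating threshold
is the MCC-maximizing point of the pooled score sweep.
"""

from il17pred import GeneratorConfig, SVMConfig, generate_corpus, kfold_cv

corpus = generate_corpus(GeneratorConfig(seed=1))
print(f"corpus: {corpus.n_pos} positives / {corpus.n_neg} negatives\n")

for feature in ("AAC", "DPC"):
    report = kfold_cv(
        corpus, feature, "SVM", SVMConfig(kernel="polynomial", d=2), k=10, seed=1
    )
    m = report.pooled_metrics
    print(
        f"{feature}: ACC={m.ACC:5.1f}%  MCC={m.MCC:.3f}  AUC={report.auc:.3f}"
        f"  (best threshold {report.best_threshold:+.2f})"
    )

print(
    "\nDipeptide composition sees residue *arrangement* (the planted LL/SL/"
    "\nLK transitions), so its MCC is at least that of plain composition."
)
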