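"""Descriptive composition and positional-conservation statistics.

Compares the two classes of a labeled epitope corpus:

* :func:`compare_composition` — per-residue or per-dipeptide percent
  composition of each peptide, compared between classes with Welch's
  unequal-variance t-test. No multiple-testing correction is applied by
  default (an optional Bonferroni flag exists); with 400 dipeptides at
  alpha = 0.01 about four false positives are expected under the null.
* :func:`terminal_enrichment` — residue frequencies at the five N-terminal
  and five C-terminal positions, compared between classes by a
  two-proportion z-test (a tabular two-sample-logo analysis; no graphics).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .alphabet import AMINO_ACIDS, DIPEPTIDES
from .dataio import EpitopeDataset
from .features import extract_aac, extract_dpc


@dataclass(frozen=True)
class CompositionComparison:
    feature: str  # residue or dipeptide
    mean_pos: float  # mean percent composition in positives
    mean_neg: float
    t: float
    df: float
    p: float
    significant: bool


@dataclass(frozen=True)
class PositionalEnrichment:
    position: str  # N1..N5 / C5..C1
    residue: str
    freq_pos: float
    freq_neg: float
    z: float
    p: float
    direction: str  # "enriched" (in positives) or "depleted"
    significant: bool


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, Welch-Satterthwaite df,
    two-sided p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("both samples have zero variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_composition(
    dataset: EpitopeDataset,
    granularity: str = "residue",
    alpha: float = 0.01,
    bonferroni: bool = False,
) -> list[CompositionComparison]:
    """Per-feature Welch's t-test between the per-peptide percent
    compositions of positives and negatives.

    Output is sorted with significant features first, by decreasing
    |mean difference|, so "top N most abundant and significant" lists can
    be read off the head directly.
    """
    if granularity == "residue":
        names = list(AMINO_ACIDS)
        extract = extract_aac
        peptides_pos = dataset.positives
        peptides_neg = dataset.negatives
    elif granularity == "dipeptide":
        names = list(DIPEPTIDES)
        extract = extract_dpc
        peptides_pos = [p for p in dataset.positives if len(p) >= 2]
        peptides_neg = [p for p in dataset.negatives if len(p) >= 2]
    else:
        raise ValueError("granularity must be 'residue' or 'dipeptide'")
    if len(peptides_pos) < 2 or len(peptides_neg) < 2:
        raise ValueError("each class needs at least 2 eligible peptides")

    X_pos = np.array([extract(p).values for p in peptides_pos])
    X_neg = np.array([extract(p).values for p in peptides_neg])
    cutoff = alpha / len(names) if bonferroni else alpha

    out = []
    for k, name in enumerate(names):
        a, b = X_pos[:, k], X_neg[:, k]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
            t, df, p = 0.0, float(len(a) + len(b) - 2), 1.0
        else:
            t, df, p = welch_t(a, b)
        out.append(
            CompositionComparison(
                feature=name,
                mean_pos=float(a.mean()),
                mean_neg=float(b.mean()),
                t=t,
                df=df,
                p=p,
                significant=bool(p < cutoff),
            )
        )
    out.sort(key=lambda c: (not c.significant, -abs(c.mean_pos - c.mean_neg)))
    return out


def top_enriched(
    comparisons: Sequence[CompositionComparison], in_positives: bool, n: int = 10
) -> list[str]:
    """The n most abundant significant features of one class."""
    sign = 1 if in_positives else -1
    rows = [
        c for c in comparisons if c.significant and sign * (c.mean_pos - c.mean_neg) > 0
    ]
    rows.sort(key=lambda c: -abs(c.mean_pos - c.mean_neg))
    return [c.feature for c in rows[:n]]


MIN_TERMINAL_PEPTIDE_LEN = 10  # shorter peptides would double-count termini


def terminal_enrichment(
    dataset: EpitopeDataset, n_terminal: int = 5, alpha: float = 0.05
) -> tuple[list[PositionalEnrichment], int]:
    """Per-position residue enrichment at both termini.

    Positions N1..N5 count from the N-terminus, C5..C1 from the C-terminus
    (C1 = last residue). Peptides shorter than 2 * n_terminal are skipped;
    the skip count is returned alongside the table. Frequencies are
    compared per residue and position by a two-proportion z-test.
    """
    min_len = 2 * n_terminal
    pos = [p for p in dataset.positives if len(p) >= min_len]
    neg = [p for p in dataset.negatives if len(p) >= min_len]
    skipped = (dataset.n_pos - len(pos)) + (dataset.n_neg - len(neg))
    if not pos or not neg:
        raise ValueError(
            f"no peptides of length >= {min_len} in one of the classes"
        )

    labels = [f"N{i}" for i in range(1, n_terminal + 1)] + [
        f"C{i}" for i in range(n_terminal, 0, -1)
    ]

    def residue_at(seq: str, label: str) -> str:
        if label.startswith("N"):
            return seq[int(label[1:]) - 1]
        return seq[-int(label[1:])]

    out = []
    for label in labels:
        res_pos = [residue_at(p.seq, label) for p in pos]
        res_neg = [residue_at(p.seq, label) for p in neg]
        for aa in AMINO_ACIDS:
            k_pos = sum(1 for r in res_pos if r == aa)
            k_neg = sum(1 for r in res_neg if r == aa)
            f_pos = k_pos / len(pos)
            f_neg = k_neg / len(neg)
            if k_pos + k_neg == 0 or (k_pos == len(pos) and k_neg == len(neg)):
                z, p_val = 0.0, 1.0
            else:
                z, p_val = proportions_ztest(
                    [k_pos, k_neg], [len(pos), len(neg)]
                )
            out.append(
                PositionalEnrichment(
                    position=label,
                    residue=aa,
                    freq_pos=f_pos,
                    freq_neg=f_neg,
                    z=float(z),
                    p=float(p_val),
                    direction="enriched" if f_pos >= f_neg else "depleted",
                    significant=bool(p_val < alpha),
                )
            )
    return out, skipped


def write_composition_table(
    comparisons: Sequence[CompositionComparison], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("feature\tmean_pos\tmean_neg\tt\tdf\tp\tsignificant\n")
        for c in comparisons:
            fh.write(
                f"{c.feature}\t{c.mean_pos:.4f}\t{c.mean_neg:.4f}\t"
                f"{c.t:.4f}\t{c.df:.2f}\t{c.p:.3e}\t{int(c.significant)}\n"
            )


def write_enrichment_table(
    rows: Sequence[PositionalEnrichment], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# test: two-proportion z-test\n")
        fh.write("position\tresidue\tfreq_pos\tfreq_neg\tz\tp\tdirection\tsignificant\n")
        for r in rows:
            fh.write(
                f"{r.position}\t{r.residue}\t{r.freq_pos:.4f}\t{r.freq_neg:.4f}\t"
                f"{r.z:.4f}\t{r.p:.3e}\t{r.direction}\t{int(r.significant)}\n"
            )
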