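"""Sequence-composition feature extraction.

Three fixed-length representations of a peptide:

* **AAC** — amino acid composition: the percentage of each of the 20
  residues in the peptide (vector length 20, sums to 100).
* **DPC** — dipeptide composition: the percentage of each of the 400
  overlapping adjacent residue pairs (a peptide of length L has L-1
  dipeptides; vector length 400, sums to 100).
* **AAP** — amino-acid-pair propensity feature: DPC weighted per dipeptide
  by a propensity learned from a labeled corpus. The propensity of
  dipeptide d is the log-ratio ln(f+(d) / f-(d)) of its smoothed relative
  frequency in positives vs negatives, rescaled by the maximum absolute
  value so every weight lies in [-1, +1]. The AAP entry for d is then
  (DPC_d / 100) * weight_d, so every entry has magnitude <= 1.

Feature columns follow the canonical orderings in :mod:`il17pred.alphabet`.
"""

from __future__ import annotations

import csv
import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, DIPEPTIDE_INDEX, DIPEPTIDES
from .dataio import EpitopeDataset, Peptide

FEATURE_KINDS = ("AAC", "DPC", "AAP")
FEATURE_DIM = {"AAC": 20, "DPC": 400, "AAP": 400}


@dataclass(frozen=True)
class FeatureVector:
    kind: str
    values: np.ndarray

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(AMINO_ACIDS) if self.kind == "AAC" else DIPEPTIDES


@dataclass(frozen=True)
class AAPWeights:
    """Trained 400-entry dipeptide propensity table in canonical order."""

    weights: np.ndarray
    pseudocount: float
    source: str  # fingerprint of the training corpus

    def __post_init__(self) -> None:
        if self.weights.shape != (400,):
            raise ValueError("AAP weights must have exactly 400 entries")


def extract_aac(peptide: Peptide) -> FeatureVector:
    """Percent composition of the 20 residues, canonical order."""
    counts = np.zeros(20)
    for c in peptide.seq:
        counts[AA_INDEX[c]] += 1
    return FeatureVector("AAC", counts / len(peptide.seq) * 100.0)


def extract_dpc(peptide: Peptide) -> FeatureVector:
    """Percent composition of the 400 overlapping dipeptides."""
    if len(peptide.seq) < 2:
        raise ValueError(f"peptide {peptide.id!r}: DPC needs length >= 2")
    counts = np.zeros(400)
    for i in range(len(peptide.seq) - 1):
        counts[DIPEPTIDE_INDEX[peptide.seq[i : i + 2]]] += 1
    return FeatureVector("DPC", counts / (len(peptide.seq) - 1) * 100.0)


def _dipeptide_counts(peptides: Iterable[Peptide]) -> np.ndarray:
    counts = np.zeros(400)
    for pep in peptides:
        for i in range(len(pep.seq) - 1):
            counts[DIPEPTIDE_INDEX[pep.seq[i : i + 2]]] += 1
    return counts


def corpus_fingerprint(dataset: EpitopeDataset) -> str:
    h = hashlib.sha256()
    for pep in dataset.positives:
        h.update(b"+" + pep.seq.encode())
    for pep in dataset.negatives:
        h.update(b"-" + pep.seq.encode())
    return h.hexdigest()[:16]


def train_aap_weights(
    dataset: EpitopeDataset, pseudocount: float = 1.0
) -> AAPWeights:
    """Learn dipeptide propensities from a labeled corpus.

    f+(d) = (count of d in positives + pseudocount) /
            (total positive dipeptides + 400 * pseudocount), f-(d) analogous;
    raw weight w(d) = ln(f+(d) / f-(d)); weights rescaled by max|w| into
    [-1, +1]. Add-one smoothing by default keeps the log finite.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    pos_counts = _dipeptide_counts(dataset.positives)
    neg_counts = _dipeptide_counts(dataset.negatives)
    if pos_counts.sum() == 0 or neg_counts.sum() == 0:
        raise ValueError("a class has zero total dipeptides")
    f_pos = (pos_counts + pseudocount) / (pos_counts.sum() + 400 * pseudocount)
    f_neg = (neg_counts + pseudocount) / (neg_counts.sum() + 400 * pseudocount)
    raw = np.log(f_pos / f_neg)
    scale = np.abs(raw).max()
    weights = raw / scale if scale > 0 else raw
    return AAPWeights(weights, pseudocount, corpus_fingerprint(dataset))


def extract_aap(peptide: Peptide, weights: AAPWeights) -> FeatureVector:
    """DPC fractions weighted by trained propensities: entry_d = (DPC_d/100) * w_d."""
    dpc = extract_dpc(peptide)
    return FeatureVector("AAP", dpc.values / 100.0 * weights.weights)


def feature_matrix(
    peptides: Sequence[Peptide],
    kind: str,
    aap_weights: AAPWeights | None = None,
) -> np.ndarray:
    """Stack feature vectors for a peptide list into an (n, dim) array."""
    if kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {kind!r}")
    if kind == "AAC":
        rows = [extract_aac(p).values for p in peptides]
    elif kind == "DPC":
        rows = [extract_dpc(p).values for p in peptides]
    else:
        if aap_weights is None:
            raise ValueError("AAP features require trained weights")
        rows = [extract_aap(p, aap_weights).values for p in peptides]
    return np.array(rows) if rows else np.empty((0, FEATURE_DIM[kind]))


def save_aap_weights(weights: AAPWeights, path: str | Path) -> None:
    """400-row TSV with a metadata header (pseudocount, corpus fingerprint)."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# pseudocount\t{weights.pseudocount}\n")
        fh.write(f"# source\t{weights.source}\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["dipeptide", "weight"])
        for d, w in zip(DIPEPTIDES, weights.weights):
            writer.writerow([d, repr(float(w))])


def load_aap_weights(path: str | Path) -> AAPWeights:
    pseudocount = math.nan
    source = ""
    values: dict[str, float] = {}
    with open(path, newline="") as fh:
        for line in fh:
            if line.startswith("# pseudocount"):
                pseudocount = float(line.split("\t")[1])
            elif line.startswith("# source"):
                source = line.split("\t")[1].strip()
            elif line.startswith("#") or line.startswith("dipeptide"):
                continue
            else:
                d, w = line.rstrip("\n").split("\t")
                values[d] = float(w)
    if len(values) != 400 or math.isnan(pseudocount):
        raise ValueError(f"malformed AAP weight file {path}")
    return AAPWeights(
        np.array([values[d] for d in DIPEPTIDES]), pseudocount, source
    )


def write_feature_table(
    peptides: Sequence[Peptide],
    kind: str,
    path: str | Path,
    aap_weights: AAPWeights | None = None,
) -> None:
    """Export a feature matrix as TSV, rows = peptides, canonical columns."""
    mat = feature_matrix(peptides, kind, aap_weights)
    names = list(AMINO_ACIDS) if kind == "AAC" else list(DIPEPTIDES)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["id"] + names)
        for pep, row in zip(peptides, mat):
            writer.writerow([pep.id] + [f"{v:.6g}" for v in row])
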