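"""Sequence I/O and dataset curation.

Reads peptides and proteins from FASTA or labeled TSV, validates them
against the 20-letter amino acid alphabet, and applies the curation rules
used to assemble an epitope training corpus: a 5-30 residue length filter,
within-class deduplication, removal of negatives that exactly match a
positive, and a seeded stratified train/validation split.
"""

from __future__ import annotations

import csv
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import invalid_residues

DEFAULT_MIN_LEN = 5
DEFAULT_MAX_LEN = 30


class CurationError(ValueError):
    """Raised when curation leaves a class empty (unusable corpus)."""


@dataclass(frozen=True)
class Peptide:
    """A validated amino acid sequence with a free-text identifier."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        bad = invalid_residues(seq)
        if not seq:
            raise ValueError(f"peptide {self.id!r}: empty sequence")
        if bad:
            pos, char = bad[0]
            raise ValueError(
                f"peptide {self.id!r}: invalid residue {char!r} at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class EpitopeDataset:
    """Labeled peptide corpus: positives (inducers) and negatives.

    ``curation_log`` records, in order, every curation rule applied and the
    number of records it removed.
    """

    positives: list[Peptide]
    negatives: list[Peptide]
    curation_log: list[tuple[str, int]] = field(default_factory=list)

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)

    def all_peptides(self) -> list[Peptide]:
        return list(self.positives) + list(self.negatives)

    def labels(self) -> list[int]:
        return [1] * self.n_pos + [0] * self.n_neg


@dataclass
class SplitDataset:
    train: EpitopeDataset
    validation: EpitopeDataset
    seed: int
    train_fraction: float


def read_fasta(path: str | Path, strict: bool = True) -> list[Peptide]:
    """Read peptides from a FASTA file, uppercasing sequences.

    In strict mode a record with a character outside the 20-letter alphabet
    raises; otherwise such records are skipped. Duplicate ids always raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    peptides: list[Peptide] = []
    seen_ids: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen_ids:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen_ids.add(rec.id)
        seq = str(rec.seq).upper()
        bad = invalid_residues(seq)
        if bad or not seq:
            if strict:
                pos, char = bad[0] if bad else (0, "")
                raise ValueError(
                    f"record {rec.id!r}: invalid residue {char!r} at position {pos + 1}"
                )
            continue
        peptides.append(Peptide(rec.id, seq))
    if not peptides and not seen_ids:
        raise ValueError(f"no FASTA records in {path}")
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    records = [SeqRecord(Seq(p.seq), id=p.id, description="") for p in peptides]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_labeled_tsv(path: str | Path, strict: bool = True) -> EpitopeDataset:
    """Read a labeled corpus from TSV with columns id, sequence, label (1/0)."""
    path = Path(path)
    positives: list[Peptide] = []
    negatives: list[Peptide] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise ValueError(f"empty TSV {path}")
        for row in reader:
            if not row:
                continue
            pid, seq, label = row[0], row[1], row[2]
            try:
                pep = Peptide(pid, seq)
            except ValueError:
                if strict:
                    raise
                continue
            (positives if label.strip() == "1" else negatives).append(pep)
    return EpitopeDataset(positives, negatives)


def write_labeled_tsv(dataset: EpitopeDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["id", "sequence", "label"])
        for pep in dataset.positives:
            writer.writerow([pep.id, pep.seq, 1])
        for pep in dataset.negatives:
            writer.writerow([pep.id, pep.seq, 0])


def write_curation_log(dataset: EpitopeDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["rule", "records_removed"])
        writer.writerows(dataset.curation_log)


def length_filter(
    peptides: Sequence[Peptide],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[Peptide], int]:
    """Keep peptides with min_len <= length <= max_len (inclusive bounds)."""
    if not (1 <= min_len <= max_len):
        raise ValueError(f"invalid length bounds [{min_len}, {max_len}]")
    kept = [p for p in peptides if min_len <= len(p) <= max_len]
    return kept, len(peptides) - len(kept)


def dedup_and_remove_overlap(
    positives: Sequence[Peptide], negatives: Sequence[Peptide]
) -> EpitopeDataset:
    """Collapse exact duplicates within each class, then drop every negative
    whose sequence exactly matches a positive.

    Comparison is exact, case-normalized string equality; the first
    occurrence of a duplicated sequence is kept. The curation log records
    the records removed by each rule.
    """
    log: list[tuple[str, int]] = []

    def dedup(peps: Sequence[Peptide]) -> list[Peptide]:
        seen: set[str] = set()
        out = []
        for p in peps:
            if p.seq not in seen:
                seen.add(p.seq)
                out.append(p)
        return out

    pos = dedup(positives)
    log.append(("dedup_positives", len(positives) - len(pos)))
    neg = dedup(negatives)
    log.append(("dedup_negatives", len(negatives) - len(neg)))

    pos_seqs = {p.seq for p in pos}
    neg_clean = [p for p in neg if p.seq not in pos_seqs]
    log.append(("remove_pos_neg_overlap", len(neg) - len(neg_clean)))

    if not pos or not neg_clean:
        raise CurationError(
            f"curation left an empty class (positives={len(pos)}, "
            f"negatives={len(neg_clean)})"
        )
    return EpitopeDataset(pos, neg_clean, log)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def random_split(
    dataset: EpitopeDataset,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> SplitDataset:
    """Seeded random train/validation split.

    When stratified (default) each class is split independently with a train
    count of round(train_fraction * class size), rounding half away from
    zero. Deterministic given the seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")

    rng = random.Random(seed)

    def split_class(peps: list[Peptide]) -> tuple[list[Peptide], list[Peptide]]:
        if len(peps) < 2:
            raise ValueError("class too small to populate both partitions")
        idx = list(range(len(peps)))
        rng.shuffle(idx)
        n_train = _round_half_away(train_fraction * len(peps))
        n_train = min(max(n_train, 1), len(peps) - 1)
        train_idx = sorted(idx[:n_train])
        val_idx = sorted(idx[n_train:])
        return [peps[i] for i in train_idx], [peps[i] for i in val_idx]

    if stratified:
        tr_pos, va_pos = split_class(list(dataset.positives))
        tr_neg, va_neg = split_class(list(dataset.negatives))
    else:
        pooled = [(p, 1) for p in dataset.positives] + [(p, 0) for p in dataset.negatives]
        idx = list(range(len(pooled)))
        rng.shuffle(idx)
        n_train = _round_half_away(train_fraction * len(pooled))
        n_train = min(max(n_train, 1), len(pooled) - 1)
        train_set = set(idx[:n_train])
        tr_pos = [p for i, (p, y) in enumerate(pooled) if i in train_set and y == 1]
        tr_neg = [p for i, (p, y) in enumerate(pooled) if i in train_set and y == 0]
        va_pos = [p for i, (p, y) in enumerate(pooled) if i not in train_set and y == 1]
        va_neg = [p for i, (p, y) in enumerate(pooled) if i not in train_set and y == 0]

    return SplitDataset(
        train=EpitopeDataset(tr_pos, tr_neg),
        validation=EpitopeDataset(va_pos, va_neg),
        seed=seed,
        train_fraction=train_fraction,
    )
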