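"""Application modes built on a trained model.

* :func:`pep_pred` — classify individual peptides (5-30 residues).
* :func:`pep_scan` — slide a fixed-length window along full-length proteins
  and score every window, flagging antigenic regions.
* :func:`metag_scan` — scan translated metagenomic reads: each read is
  segmented at any character outside the 20-letter alphabet (stops, X) and
  segments long enough to hold a window are scanned; positive windows can
  be exported as FASTA for downstream similarity search (e.g. BLASTP).
* :func:`substitution_scan` — virtual screening: score every single-residue
  variant of a peptide to map position-specific effects on the predicted
  response.

All coordinates are 1-based inclusive on the query sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .alphabet import AMINO_ACIDS
from .dataio import Peptide, write_fasta
from .models import TrainedModel, decision_scores

PEPTIDE_MIN_LEN = 5
PEPTIDE_MAX_LEN = 30
DEFAULT_WINDOW = 15


@dataclass(frozen=True)
class WindowHit:
    query_id: str
    start: int  # 1-based inclusive
    end: int
    window_seq: str
    score: float
    label: str  # "inducer" / "non-inducer"


@dataclass
class SubstitutionScan:
    parent: Peptide
    parent_score: float
    threshold: float
    # dense L x 20 matrix in canonical residue order; the cell for the
    # original residue holds the parent score (self substitution)
    scores: np.ndarray

    def delta(self) -> np.ndarray:
        return self.scores - self.parent_score


def pep_pred(
    model: TrainedModel,
    peptides: Sequence[Peptide],
    threshold: float | None = None,
) -> list[dict]:
    """Classify peptides of length 5-30; out-of-range records get a
    per-record error message and the rest are still processed."""
    thr = model.threshold if threshold is None else threshold
    valid, rows = [], []
    for pep in peptides:
        if not PEPTIDE_MIN_LEN <= len(pep) <= PEPTIDE_MAX_LEN:
            rows.append(
                {
                    "id": pep.id,
                    "sequence": pep.seq,
                    "score": None,
                    "label": None,
                    "threshold": thr,
                    "error": f"length {len(pep)} outside "
                    f"[{PEPTIDE_MIN_LEN}, {PEPTIDE_MAX_LEN}]",
                }
            )
        else:
            valid.append(pep)
            rows.append(None)
    scores = decision_scores(model, valid) if valid else []
    it = iter(zip(valid, scores))
    out = []
    for row in rows:
        if row is not None:
            out.append(row)
            continue
        pep, s = next(it)
        out.append(
            {
                "id": pep.id,
                "sequence": pep.seq,
                "score": float(s),
                "label": "inducer" if s >= thr else "non-inducer",
                "threshold": thr,
                "error": None,
            }
        )
    return out


def _scan_segment(
    model: TrainedModel,
    query_id: str,
    seq: str,
    offset: int,
    window: int,
    thr: float,
) -> list[WindowHit]:
    n_windows = len(seq) - window + 1
    windows = [
        Peptide(f"{query_id}|{offset + i + 1}", seq[i : i + window])
        for i in range(n_windows)
    ]
    scores = decision_scores(model, windows)
    hits = []
    for i, s in enumerate(scores):
        start = offset + i + 1
        hits.append(
            WindowHit(
                query_id=query_id,
                start=start,
                end=start + window - 1,
                window_seq=seq[i : i + window],
                score=float(s),
                label="inducer" if s >= thr else "non-inducer",
            )
        )
    return hits


def pep_scan(
    model: TrainedModel,
    proteins: Sequence[Peptide],
    window: int = DEFAULT_WINDOW,
    threshold: float | None = None,
    merge_overlaps: bool = False,
) -> list[WindowHit]:
    """Score all overlapping windows (step 1) of each protein.

    Returns every window with its score; windows at or above the threshold
    are labeled "inducer". With ``merge_overlaps`` adjacent/overlapping
    positive windows are merged into single region hits (off by default:
    per-window reporting is the primary output).
    """
    if not PEPTIDE_MIN_LEN <= window <= PEPTIDE_MAX_LEN:
        raise ValueError(f"window must be in [{PEPTIDE_MIN_LEN}, {PEPTIDE_MAX_LEN}]")
    thr = model.threshold if threshold is None else threshold
    hits: list[WindowHit] = []
    for prot in proteins:
        if len(prot) < window:
            raise ValueError(
                f"protein {prot.id!r} (length {len(prot)}) shorter than window {window}"
            )
        hits.extend(_scan_segment(model, prot.id, prot.seq, 0, window, thr))
    if merge_overlaps:
        hits = _merge_positive_windows(hits)
    return hits


def _merge_positive_windows(hits: list[WindowHit]) -> list[WindowHit]:
    """Union overlapping positive windows per query; negatives dropped."""
    merged: list[WindowHit] = []
    by_query: dict[str, list[WindowHit]] = {}
    for h in hits:
        if h.label == "inducer":
            by_query.setdefault(h.query_id, []).append(h)
    for qid, qhits in by_query.items():
        qhits.sort(key=lambda h: (h.start, h.end))
        cur = qhits[0]
        cur_seq = cur.window_seq
        for h in qhits[1:]:
            if h.start <= cur.end + 1:
                if h.end > cur.end:
                    cur_seq = cur_seq + h.window_seq[cur.end - h.start + 1 :]
                cur = WindowHit(
                    qid, cur.start, max(cur.end, h.end), cur_seq,
                    max(cur.score, h.score), "inducer",
                )
            else:
                merged.append(cur)
                cur = h
                cur_seq = h.window_seq
        merged.append(cur)
    return merged


_SEGMENT_RE = re.compile("[" + AMINO_ACIDS + "]+")


def segment_read(seq: str) -> list[tuple[int, str]]:
    """Split a read at non-standard characters; returns (0-based offset,
    segment) pairs."""
    return [(m.start(), m.group()) for m in _SEGMENT_RE.finditer(seq.upper())]


def metag_scan(
    model: TrainedModel,
    reads: Sequence[tuple[str, str]],
    window: int = DEFAULT_WINDOW,
    threshold: float | None = None,
) -> tuple[list[WindowHit], list[Peptide], list[dict]]:
    """Scan translated metagenomic reads for predicted inducer windows.

    ``reads`` are (id, sequence) pairs; sequences may contain stops (*) or
    ambiguity codes, at which the read is segmented. Returns (all window
    hits, positive windows as exportable peptides, per-read summaries).
    """
    thr = model.threshold if threshold is None else threshold
    hits: list[WindowHit] = []
    summaries: list[dict] = []
    for rid, seq in reads:
        segments = [(off, s) for off, s in segment_read(seq) if len(s) >= window]
        read_hits: list[WindowHit] = []
        for off, s in segments:
            read_hits.extend(_scan_segment(model, rid, s, off, window, thr))
        n_positive = sum(1 for h in read_hits if h.label == "inducer")
        summaries.append(
            {
                "read_id": rid,
                "segments_scanned": len(segments),
                "windows": len(read_hits),
                "positive_windows": n_positive,
            }
        )
        hits.extend(read_hits)
    positives = [
        Peptide(f"{h.query_id}|{h.start}-{h.end}", h.window_seq)
        for h in hits
        if h.label == "inducer"
    ]
    return hits, positives, summaries


def export_positive_windows(positives: Sequence[Peptide], path: str | Path) -> None:
    """FASTA export of predicted inducer windows for external BLASTP."""
    write_fasta(positives, path)


def substitution_scan(
    model: TrainedModel,
    peptide: Peptide,
    threshold: float | None = None,
) -> SubstitutionScan:
    """Score every single-residue substitution of ``peptide``.

    Produces a dense L x 20 matrix in canonical residue order; the cell of
    the original residue at each position holds the parent score, so the
    matrix has exactly L x 19 true variants.
    """
    thr = model.threshold if threshold is None else threshold
    parent_score = float(decision_scores(model, [peptide])[0])
    L = len(peptide.seq)
    variants: list[Peptide] = []
    slots: list[tuple[int, int]] = []
    for i in range(L):
        for a_idx, a in enumerate(AMINO_ACIDS):
            if a == peptide.seq[i]:
                continue
            variants.append(
                Peptide(f"{peptide.id}|{peptide.seq[i]}{i + 1}{a}",
                        peptide.seq[:i] + a + peptide.seq[i + 1 :])
            )
            slots.append((i, a_idx))
    scores = decision_scores(model, variants)
    mat = np.full((L, 20), parent_score)
    for (i, a_idx), s in zip(slots, scores):
        mat[i, a_idx] = s
    return SubstitutionScan(peptide, parent_score, thr, mat)


def write_window_hits(hits: Sequence[WindowHit], path: str | Path) -> None:
    """TSV hit table; coordinates 1-based inclusive."""
    with open(path, "w", newline="") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write("query_id\tstart\tend\tpeptide\tscore\tlabel\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.start}\t{h.end}\t{h.window_seq}\t"
                f"{h.score:.6g}\t{h.label}\n"
            )


def write_substitution_scan(scan: SubstitutionScan, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# parent\t{scan.parent.id}\t{scan.parent.seq}\n")
        fh.write(f"# parent_score\t{scan.parent_score:.6g}\n")
        fh.write("position\toriginal\t" + "\t".join(AMINO_ACIDS) + "\n")
        for i, row in enumerate(scan.scores):
            fh.write(
                f"{i + 1}\t{scan.parent.seq[i]}\t"
                + "\t".join(f"{v:.6g}" for v in row)
                + "\n"
            )
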