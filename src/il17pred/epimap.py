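"""Epitope mapping onto query sequences.

Two complementary modes:

* :func:`exact_map` — report every exact (possibly overlapping) occurrence
  of each database epitope in each query sequence.
* :func:`smith_waterman` / :func:`sim_search` — optimal local alignment
  under affine gap penalties (Gotoh dynamic program), mapping epitopes to
  *similar* regions of the query. Defaults: BLOSUM62, gap open 10, gap
  extend 0.5 (a gap of length k costs open + extend*(k-1)).

Coordinates are 1-based inclusive on the query.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .dataio import Peptide

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class EpitopeMatch:
    epitope_id: str
    query_id: str
    start: int  # 1-based inclusive on query
    end: int
    kind: str  # "exact" or "local-alignment"
    score: float | None  # alignment score; None for exact matches
    identity: float


@dataclass(frozen=True)
class AlignmentHit:
    epitope_id: str
    query_id: str
    aligned_epitope: str  # with gap dashes
    aligned_query: str
    score: float
    start: int  # 1-based inclusive on query
    end: int
    identity: float


def load_substitution_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


def exact_map(
    epitope_db: Sequence[Peptide], queries: Sequence[Peptide]
) -> list[EpitopeMatch]:
    """Every exact occurrence (including overlapping ones) of every epitope
    in every query, ordered by (query, position, epitope id)."""
    if not epitope_db or not queries:
        raise ValueError("exact_map requires a non-empty database and queries")
    matches = []
    for q in queries:
        for epi in epitope_db:
            start = q.seq.find(epi.seq)
            while start != -1:
                matches.append(
                    EpitopeMatch(
                        epitope_id=epi.id,
                        query_id=q.id,
                        start=start + 1,
                        end=start + len(epi.seq),
                        kind="exact",
                        score=None,
                        identity=1.0,
                    )
                )
                start = q.seq.find(epi.seq, start + 1)
    order = {q.id: i for i, q in enumerate(queries)}
    matches.sort(key=lambda m: (order[m.query_id], m.start, m.epitope_id))
    return matches


def smith_waterman(
    a: Peptide,
    b: Peptide,
    matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentHit | None:
    """Optimal local alignment of epitope ``a`` against query ``b``.

    Affine gaps: a run of k gap positions costs gap_open + gap_extend*(k-1).
    Traceback starts at the highest-scoring cell with the smallest (i, j);
    at equal-scoring moves the preference is diagonal > up (gap in query) >
    left (gap in epitope). A maximal score of 0 means no local similarity
    and is reported as no hit (None).
    """
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be > 0")
    if matrix is None:
        matrix = load_substitution_matrix()
    sa, sb = a.seq, b.seq
    n, m = len(sa), len(sb)

    def sub(x: str, y: str) -> float:
        try:
            return float(matrix[x, y])
        except (KeyError, IndexError) as exc:
            raise ValueError(f"residue pair ({x}, {y}) absent from matrix") from exc

    # Gotoh: H best score ending at (i, j); E gap in epitope a (left moves),
    # F gap in query b (up moves)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), _NEG_INF)
    F = np.full((n + 1, m + 1), _NEG_INF)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            H[i, j] = max(
                0.0, H[i - 1, j - 1] + sub(sa[i - 1], sb[j - 1]), E[i, j], F[i, j]
            )

    best = H.max()
    if best <= 0:
        return None
    # smallest (i, j) among maxima
    i, j = np.argwhere(H == best)[0]
    i, j = int(i), int(j)

    al_a: list[str] = []
    al_b: list[str] = []
    end_j = j
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            if h == H[i - 1, j - 1] + sub(sa[i - 1], sb[j - 1]):
                al_a.append(sa[i - 1])
                al_b.append(sb[j - 1])
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in query: consume a residue of the epitope
            al_a.append(sa[i - 1])
            al_b.append("-")
            if F[i, j] == H[i - 1, j] - gap_open:
                state = "H"
            i -= 1
        else:  # state == "E": gap in epitope: consume a query residue
            al_a.append("-")
            al_b.append(sb[j - 1])
            if E[i, j] == H[i, j - 1] - gap_open:
                state = "H"
            j -= 1

    aligned_a = "".join(reversed(al_a))
    aligned_b = "".join(reversed(al_b))
    pairs = [
        (x, y) for x, y in zip(aligned_a, aligned_b) if x != "-" and y != "-"
    ]
    identity = (
        sum(1 for x, y in pairs if x == y) / len(pairs) if pairs else 0.0
    )
    return AlignmentHit(
        epitope_id=a.id,
        query_id=b.id,
        aligned_epitope=aligned_a,
        aligned_query=aligned_b,
        score=float(best),
        start=j + 1,
        end=end_j,
        identity=identity,
    )


def sim_search(
    epitope_db: Sequence[Peptide],
    queries: Sequence[Peptide],
    min_score: float = 0.0,
    min_identity: float = 0.0,
    matrix=None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> list[AlignmentHit]:
    """Run Smith-Waterman for every (epitope, query) pair and keep hits with
    score >= min_score and identity >= min_identity, sorted by descending
    score. Epitope ids are carried through verbatim."""
    if min_score < 0 or min_identity < 0:
        raise ValueError("thresholds must be non-negative")
    if matrix is None:
        matrix = load_substitution_matrix()
    hits = []
    for epi in epitope_db:
        for q in queries:
            hit = smith_waterman(epi, q, matrix, gap_open, gap_extend)
            if hit is None:
                continue
            if hit.score >= min_score and hit.identity >= min_identity:
                hits.append(hit)
    hits.sort(key=lambda h: (-h.score, h.query_id, h.start, h.epitope_id))
    return hits


def write_matches(matches: Sequence[EpitopeMatch], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# coordinates are 1-based inclusive on the query\n")
        fh.write("epitope_id\tquery_id\tstart\tend\tkind\tscore\tidentity\n")
        for m in matches:
            score = "" if m.score is None else f"{m.score:.6g}"
            fh.write(
                f"{m.epitope_id}\t{m.query_id}\t{m.start}\t{m.end}\t"
                f"{m.kind}\t{score}\t{m.identity:.4f}\n"
            )


def write_alignment_hits(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# coordinates are 1-based inclusive on the query\n")
        fh.write(
            "epitope_id\tquery_id\tstart\tend\tscore\tidentity\t"
            "aligned_epitope\taligned_query\n"
        )
        for h in hits:
            fh.write(
                f"{h.epitope_id}\t{h.query_id}\t{h.start}\t{h.end}\t"
                f"{h.score:.6g}\t{h.identity:.4f}\t{h.aligned_epitope}\t"
                f"{h.aligned_query}\n"
            )
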