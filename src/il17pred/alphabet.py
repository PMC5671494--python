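"""Canonical amino acid and dipeptide orderings shared across the package.

Feature columns everywhere follow the alphabetical residue order
``A, C, D, ..., Y`` and the row-major dipeptide order ``AA, AC, ..., YY``
(first residue major). These orderings are frozen and written into model
metadata so serialized feature columns stay portable.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 standard residues in canonical (alphabetical) order."""

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

DIPEPTIDES: tuple[str, ...] = tuple(a + b for a in AMINO_ACIDS for b in AMINO_ACIDS)
"""All 400 dipeptides, first residue major."""

DIPEPTIDE_INDEX: dict[str, int] = {d: i for i, d in enumerate(DIPEPTIDES)}

VALID_RESIDUES = frozenset(AMINO_ACIDS)


def is_valid_sequence(seq: str) -> bool:
    """True if ``seq`` is non-empty and uses only the 20 standard residues."""
    return bool(seq) and all(c in VALID_RESIDUES for c in seq)


def invalid_residues(seq: str) -> list[tuple[int, str]]:
    """Return (0-based position, character) for every non-standard residue."""
    return [(i, c) for i, c in enumerate(seq) if c not in VALID_RESIDUES]
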