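"""BLOSUM substitution matrices and the positive-score similarity rule.

Two residues are "similar" when their substitution score is strictly
positive.  Because every diagonal entry of the BLOSUM family is positive,
identity always implies similarity; this is what makes the "similar" pair
categories supersets of the strict category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import substitution_matrices

from .errors import ContentError

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(CANONICAL_AA)

MATRIX_NAMES = ("BLOSUM45", "BLOSUM62", "BLOSUM80")


def _check_aa(*residues: str) -> None:
    for r in residues:
        if r not in _AA_SET:
            raise ContentError(f"not a canonical amino acid: {r!r}")


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A named BLOSUM matrix with integer scores over the 20 canonical residues."""

    name: str
    _scores: dict = field(repr=False, hash=False, compare=False)

    def score(self, a: str, b: str) -> int:
        _check_aa(a, b)
        return self._scores[a, b]

    def similar(self, a: str, b: str) -> bool:
        return self.score(a, b) > 0

    def positive_partners(self, a: str) -> frozenset[str]:
        """All residues with a strictly positive score against ``a`` (includes ``a``)."""
        _check_aa(a)
        return frozenset(x for x in CANONICAL_AA if self._scores[a, x] > 0)


@lru_cache(maxsize=None)
def load_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    if isinstance(name, SubstitutionMatrix):
        return name
    key = name.upper()
    if key not in MATRIX_NAMES:
        raise ValueError(f"unsupported matrix {name!r}; choose from {MATRIX_NAMES}")
    raw = substitution_matrices.load(key)
    scores = {
        (a, b): int(raw[a, b]) for a in CANONICAL_AA for b in CANONICAL_AA
    }
    return SubstitutionMatrix(key, scores)


def blosum_score(a: str, b: str, matrix: str | SubstitutionMatrix = "BLOSUM62") -> int:
    """Published substitution score for an (ordered-irrelevant) residue pair."""
    m = matrix if isinstance(matrix, SubstitutionMatrix) else load_matrix(matrix)
    return m.score(a, b)


def similar(a: str, b: str, matrix: str | SubstitutionMatrix = "BLOSUM62") -> bool:
    """True iff the substitution score is strictly positive."""
    return blosum_score(a, b, matrix) > 0
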