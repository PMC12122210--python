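"""Homologous variant pairs at shared alignment columns.

Two annotated variants in different proteins form a homologous pair when
they map to the same column of a family alignment and both their reference
and alternate residues are at least BLOSUM-similar.  Four category modes
narrow that superset:

    strict        identical reference AND identical alternate
    similar_mut   identical reference, similar alternate
    similar_ref   similar reference, identical alternate
    similar_both  similar reference AND similar alternate

Because diagonal BLOSUM scores are positive, identity implies similarity
and strict pairs are contained in every similar category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .alignment import (
    DomainSegment,
    FamilyAlignment,
    pairwise_identity,
    position_to_column,
    residue_at_column,
)
from .matrices import SubstitutionMatrix, load_matrix
from .variants import MissenseVariant

logger = logging.getLogger(__name__)

PAIR_MODES = ("strict", "similar_mut", "similar_ref", "similar_both")


@dataclass(frozen=True)
class HomologousPair:
    """Two variants at the same alignment column, with similarity flags."""

    variant_a: MissenseVariant
    variant_b: MissenseVariant
    family_id: str
    column: int
    ref_identical: bool
    alt_identical: bool
    ref_similar: bool
    alt_similar: bool
    pair_identity: float

    @property
    def concordance(self) -> str:
        la, lb = self.variant_a.label, self.variant_b.label
        if la == "non_pathogenic" and lb == "non_pathogenic":
            return "NN"
        if la == "pathogenic" and lb == "pathogenic":
            return "PP"
        return "NP"

    def in_mode(self, mode: str) -> bool:
        if mode == "strict":
            return self.ref_identical and self.alt_identical
        if mode == "similar_mut":
            return self.ref_identical and self.alt_similar
        if mode == "similar_ref":
            return self.ref_similar and self.alt_identical
        if mode == "similar_both":
            return self.ref_similar and self.alt_similar
        raise ValueError(f"unknown mode {mode!r}; choose from {PAIR_MODES}")


def enumerate_pairs(
    alignments: Sequence[FamilyAlignment],
    annotated_variants: Sequence[MissenseVariant],
    matrix: str | SubstitutionMatrix = "BLOSUM62",
    allow_intra_protein: bool = False,
    inconsistencies: list | None = None,
) -> list[HomologousPair]:
    """All homologous pairs across families, deduplicated.

    A variant whose stated reference residue disagrees with the alignment is
    skipped and reported (appended to ``inconsistencies`` when given,
    logged otherwise).  When the same two variants co-occur at columns of
    several (overlapping) families, only the occurrence with the highest
    pair identity is kept, so downstream counts are over unique variant
    pairs.
    """
    m = load_matrix(matrix) if isinstance(matrix, str) else matrix
    by_protein: dict[str, list[MissenseVariant]] = {}
    for v in annotated_variants:
        by_protein.setdefault(v.protein_id, []).append(v)

    best: dict[frozenset, HomologousPair] = {}
    identity_cache: dict[tuple[int, int], float | None] = {}

    for aln in alignments:
        col_index: dict[int, list[tuple[DomainSegment, MissenseVariant]]] = {}
        for seg in aln.segments:
            for v in by_protein.get(seg.protein_id, ()):
                col = position_to_column(seg, v.position)
                if col is None:
                    continue
                observed = residue_at_column(seg, col)
                if observed != v.ref_aa:
                    msg = (
                        f"{v.protein_id}:{v.hgvs_p} states ref {v.ref_aa} but "
                        f"{seg.name} column {col} holds {observed}"
                    )
                    if inconsistencies is not None:
                        inconsistencies.append(msg)
                    else:
                        logger.warning("skipping inconsistent variant: %s", msg)
                    continue
                col_index.setdefault(col, []).append((seg, v))

        for col, items in col_index.items():
            for (seg_a, va), (seg_b, vb) in combinations(items, 2):
                if va.key == vb.key:
                    continue
                if not allow_intra_protein and va.protein_id == vb.protein_id:
                    continue
                ref_sim = m.similar(va.ref_aa, vb.ref_aa)
                alt_sim = m.similar(va.alt_aa, vb.alt_aa)
                if not (ref_sim and alt_sim):
                    continue
                ckey = (id(seg_a), id(seg_b))
                if ckey not in identity_cache:
                    identity_cache[ckey] = pairwise_identity(seg_a, seg_b)
                identity = identity_cache[ckey]
                if identity is None:
                    continue  # cannot happen: they co-align at `col`
                # canonical orientation for deterministic output
                if vb.key < va.key:
                    va, vb = vb, va
                pair = HomologousPair(
                    variant_a=va,
                    variant_b=vb,
                    family_id=aln.family_id,
                    column=col,
                    ref_identical=va.ref_aa == vb.ref_aa,
                    alt_identical=va.alt_aa == vb.alt_aa,
                    ref_similar=ref_sim,
                    alt_similar=alt_sim,
                    pair_identity=identity,
                )
                dkey = frozenset((va.key, vb.key))
                prev = best.get(dkey)
                if prev is None or pair.pair_identity > prev.pair_identity:
                    best[dkey] = pair

    return sorted(
        best.values(),
        key=lambda p: (p.family_id, p.column, p.variant_a.key, p.variant_b.key),
    )


def select_mode(
    pairs: Iterable[HomologousPair],
    mode: str = "strict",
    min_identity: float | None = None,
    inclusive: bool = False,
) -> list[HomologousPair]:
    """Filter pairs to one category mode, optionally above an identity floor.

    The identity comparison is strict by default (``pair_identity >
    min_identity``), matching the ">30% sequence identity" stratification;
    ``inclusive=True`` keeps pairs at exactly the threshold.
    """
    out = [p for p in pairs if p.in_mode(mode)]
    if min_identity is not None:
        if inclusive:
            out = [p for p in out if p.pair_identity >= min_identity]
        else:
            out = [p for p in out if p.pair_identity > min_identity]
    return out


def pairs_to_frame(pairs: Iterable[HomologousPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            {
                "family": p.family_id,
                "column": p.column,
                "protein_a": p.variant_a.protein_id,
                "variant_a": p.variant_a.hgvs_p,
                "label_a": p.variant_a.label,
                "protein_b": p.variant_b.protein_id,
                "variant_b": p.variant_b.hgvs_p,
                "label_b": p.variant_b.label,
                "ref_identical": p.ref_identical,
                "alt_identical": p.alt_identical,
                "ref_similar": p.ref_similar,
                "alt_similar": p.alt_similar,
                "pair_identity": p.pair_identity,
                "concordance": p.concordance,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family",
            "column",
            "protein_a",
            "variant_a",
            "label_a",
            "protein_b",
            "variant_b",
            "label_b",
            "ref_identical",
            "alt_identical",
            "ref_similar",
            "alt_similar",
            "pair_identity",
            "concordance",
        ],
    )


def write_pair_table(pairs: Iterable[HomologousPair], path: str | Path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)
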