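"""Rule-based label transfer from annotated homologous variants.

The prediction is two-staged, mirroring the distinction between molecular
and clinical effect:

* *damaging / not damaging* — does the substitution plausibly alter the
  protein's structure or function?  Decided from annotated variants at the
  query's alignment column: strict evidence (identical reference and
  alternate residues) overrides similar evidence (both BLOSUM-positive);
  within the deciding tier the majority label wins, ties broken by highest
  pair identity, exact ties declared conflicting.
* *disease-causing / non-disease-causing* — only variants in "pathogenic
  proteins" (autosomal-dominant genes with an established pathogenic
  missense burden) translate a damaging call into a clinical one.  A
  damaging variant in a recessive or X-linked gene is expected in the
  healthy population and is called non-disease-causing; an unknown gene
  context yields not_applicable.

`HomologousTransferClassifier` wraps this as a scikit-learn estimator:
``fit`` indexes annotated variants onto the family alignments, ``predict``
returns damaging calls for query variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from .alignment import (
    FamilyAlignment,
    column_to_position,
    pairwise_identity,
    position_to_column,
    residue_at_column,
)
from .errors import ConsistencyError
from .matrices import SubstitutionMatrix, load_matrix
from .variants import MissenseVariant, ProteinRecord

DAMAGING_CALLS = ("damaging", "not_damaging", "no_evidence", "conflicting")
CLINICAL_CALLS = (
    "disease_causing",
    "non_disease_causing",
    "not_applicable",
    "no_evidence",
)


@dataclass(frozen=True)
class Evidence:
    """One annotated homolog supporting (or contradicting) a query."""

    homolog: MissenseVariant
    tier: str  # strict | similar
    pair_identity: float
    label: str


@dataclass(frozen=True)
class Prediction:
    query: MissenseVariant
    damaging_call: str
    clinical_call: str
    evidence: tuple[Evidence, ...]
    protein_context: ProteinRecord | None


def find_homolog_evidence(
    query: MissenseVariant,
    alignments: Sequence[FamilyAlignment],
    annotated_variants: Sequence[MissenseVariant],
    matrix: str | SubstitutionMatrix = "BLOSUM62",
) -> list[Evidence]:
    """Annotated variants in other proteins at the query's alignment column(s).

    Evidence requires both the reference and alternate residues to be at
    least BLOSUM-similar; the tier is ``strict`` when both are identical.
    Raises ConsistencyError when the query's stated reference residue
    contradicts the alignment.
    """
    m = load_matrix(matrix) if isinstance(matrix, str) else matrix
    by_protein: dict[str, list[MissenseVariant]] = {}
    for v in annotated_variants:
        if v.label in ("pathogenic", "non_pathogenic"):
            by_protein.setdefault(v.protein_id, []).append(v)

    best: dict[tuple, Evidence] = {}
    for aln in alignments:
        for q_seg in aln.segments_for(query.protein_id):
            col = position_to_column(q_seg, query.position)
            if col is None:
                continue
            observed = residue_at_column(q_seg, col)
            if observed != query.ref_aa:
                raise ConsistencyError(
                    f"query {query.protein_id}:{query.hgvs_p} states ref "
                    f"{query.ref_aa} but {q_seg.name} column {col} holds {observed}"
                )
            for seg in aln.segments:
                if seg.protein_id == query.protein_id:
                    continue
                pos = column_to_position(seg, col)
                if pos is None:
                    continue
                for v in by_protein.get(seg.protein_id, ()):
                    if v.position != pos or v.ref_aa != residue_at_column(seg, col):
                        continue
                    if not (
                        m.similar(query.ref_aa, v.ref_aa)
                        and m.similar(query.alt_aa, v.alt_aa)
                    ):
                        continue
                    tier = (
                        "strict"
                        if query.ref_aa == v.ref_aa and query.alt_aa == v.alt_aa
                        else "similar"
                    )
                    identity = pairwise_identity(q_seg, seg)
                    ev = Evidence(
                        homolog=v,
                        tier=tier,
                        pair_identity=identity if identity is not None else 0.0,
                        label=v.label,
                    )
                    prev = best.get(v.key)
                    if prev is None or ev.pair_identity > prev.pair_identity:
                        best[v.key] = ev
    return sorted(
        best.values(), key=lambda e: (-e.pair_identity, e.tier, e.homolog.key)
    )


def _aggregate(evidence: Sequence[Evidence]) -> str:
    """Damaging call from evidence; see module docstring for the policy."""
    if not evidence:
        return "no_evidence"
    strict = [e for e in evidence if e.tier == "strict"]
    deciding = strict if strict else list(evidence)
    path = [e for e in deciding if e.label == "pathogenic"]
    nonp = [e for e in deciding if e.label == "non_pathogenic"]
    if len(path) > len(nonp):
        return "damaging"
    if len(nonp) > len(path):
        return "not_damaging"
    best_path = max((e.pair_identity for e in path), default=float("-inf"))
    best_nonp = max((e.pair_identity for e in nonp), default=float("-inf"))
    if best_path > best_nonp:
        return "damaging"
    if best_nonp > best_path:
        return "not_damaging"
    return "conflicting"


def predict_variant(
    query: MissenseVariant,
    evidence: Sequence[Evidence],
    protein_context: ProteinRecord | None,
    min_identity: float | None = None,
) -> Prediction:
    """Combine evidence and gene context into the two-stage verdict."""
    if min_identity is not None:
        evidence = [e for e in evidence if e.pair_identity > min_identity]
    damaging_call = _aggregate(evidence)

    if damaging_call in ("no_evidence", "conflicting"):
        clinical_call = "no_evidence"
    elif protein_context is None or protein_context.inheritance == "unknown":
        clinical_call = "not_applicable"
    elif protein_context.is_pathogenic_protein:
        clinical_call = (
            "disease_causing" if damaging_call == "damaging" else "non_disease_causing"
        )
    else:
        clinical_call = "non_disease_causing"
    return Prediction(
        query=query,
        damaging_call=damaging_call,
        clinical_call=clinical_call,
        evidence=tuple(evidence),
        protein_context=protein_context,
    )


def expand_predictions(
    annotated_variant: MissenseVariant,
    alignments: Sequence[FamilyAlignment],
    proteins: Mapping[str, ProteinRecord],
    matrix: str | SubstitutionMatrix = "BLOSUM62",
    tier: str = "strict",
) -> list[MissenseVariant]:
    """Project one annotated variant onto homologous positions.

    For every other protein segment carrying a residue at the variant's
    column(s): the strict tier emits the identical substitution (requires
    the column residue to equal the annotated reference); the similar tier
    emits every substitution to an alternate BLOSUM-similar to the
    annotated alternate, provided the reference residues are similar.
    Pathogenic labels are only projected into pathogenic-flagged proteins
    (elsewhere a damaging change is not disease-causing); non-pathogenic
    labels project everywhere.
    """
    if tier not in ("strict", "similar"):
        raise ValueError(f"tier must be strict or similar, got {tier!r}")
    m = load_matrix(matrix) if isinstance(matrix, str) else matrix
    src = annotated_variant
    out: dict[tuple, MissenseVariant] = {}
    for aln in alignments:
        for src_seg in aln.segments_for(src.protein_id):
            col = position_to_column(src_seg, src.position)
            if col is None:
                continue
            if residue_at_column(src_seg, col) != src.ref_aa:
                raise ConsistencyError(
                    f"{src.protein_id}:{src.hgvs_p} contradicts {src_seg.name}"
                )
            for seg in aln.segments:
                if seg.protein_id == src.protein_id:
                    continue
                residue = residue_at_column(seg, col)
                if residue is None:
                    continue
                if src.label == "pathogenic":
                    rec = proteins.get(seg.protein_id)
                    if rec is None or not rec.is_pathogenic_protein:
                        continue
                pos = column_to_position(seg, col)
                if tier == "strict":
                    if residue != src.ref_aa or src.alt_aa == residue:
                        continue
                    alts: Iterable[str] = (src.alt_aa,)
                else:
                    if not m.similar(residue, src.ref_aa):
                        continue
                    alts = sorted(
                        a for a in m.positive_partners(src.alt_aa) if a != residue
                    )
                for alt in alts:
                    v = MissenseVariant(
                        protein_id=seg.protein_id,
                        position=pos,
                        ref_aa=residue,
                        alt_aa=alt,
                        label=src.label,
                        source="user",
                    )
                    out.setdefault(v.key, v)
    return sorted(out.values(), key=lambda v: v.key)


def _as_variants(X) -> list[MissenseVariant]:
    if isinstance(X, pd.DataFrame):
        return [
            MissenseVariant(
                protein_id=str(r.protein_id),
                position=int(r.position),
                ref_aa=str(r.ref_aa).upper(),
                alt_aa=str(r.alt_aa).upper(),
                label=str(getattr(r, "label", "unannotated")),
            )
            for r in X.itertuples(index=False)
        ]
    return list(X)


class HomologousTransferClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator for homologous-variant label transfer.

    Parameters
    ----------
    alignments : sequence of FamilyAlignment
        Family alignments defining equivalent positions.
    proteins : mapping of protein_id -> ProteinRecord, optional
        Gene context used for the clinical call.
    matrix : str, default "BLOSUM62"
        Substitution matrix for the positive-score similarity rule.
    min_identity : float or None, default None
        Evidence filter: only homologs whose segments share strictly more
        than this identity are used (0.30 is the high-confidence preset).

    ``fit`` takes the annotated variants (X: sequence of MissenseVariant or
    a user-schema DataFrame; y optionally overrides their labels) and
    indexes them.  ``predict`` returns the damaging call per query;
    ``predict_detail`` returns full two-stage Prediction objects.
    """

    def __init__(
        self,
        alignments=None,
        proteins=None,
        matrix: str = "BLOSUM62",
        min_identity: float | None = None,
    ):
        self.alignments = alignments
        self.proteins = proteins
        self.matrix = matrix
        self.min_identity = min_identity

    def fit(self, X, y=None):
        if not self.alignments:
            raise ValueError("alignments must be provided before fitting")
        variants = _as_variants(X)
        if y is not None:
            labels = list(y)
            if len(labels) != len(variants):
                raise ValueError("y length does not match X")
            from dataclasses import replace

            variants = [
                replace(v, label=str(lab)) for v, lab in zip(variants, labels)
            ]
        for v in variants:
            if v.label not in ("pathogenic", "non_pathogenic"):
                raise ValueError(
                    f"annotated variant {v.protein_id}:{v.hgvs_p} has no usable "
                    f"label ({v.label!r})"
                )
        self.annotated_variants_ = tuple(variants)
        self.matrix_ = load_matrix(self.matrix)
        self.classes_ = np.array(sorted(DAMAGING_CALLS))
        self.n_features_in_ = 4  # (protein_id, position, ref_aa, alt_aa)
        return self

    def _check_fitted(self):
        if not hasattr(self, "annotated_variants_"):
            raise NotFittedError(
                "This HomologousTransferClassifier instance is not fitted yet."
            )

    def predict_detail(self, X) -> list[Prediction]:
        self._check_fitted()
        proteins = self.proteins or {}
        out = []
        for q in _as_variants(X):
            evidence = find_homolog_evidence(
                q, self.alignments, self.annotated_variants_, self.matrix_
            )
            out.append(
                predict_variant(
                    q,
                    evidence,
                    proteins.get(q.protein_id),
                    min_identity=self.min_identity,
                )
            )
        return out

    def predict(self, X) -> np.ndarray:
        return np.array([p.damaging_call for p in self.predict_detail(X)], dtype=object)

    def predict_clinical(self, X) -> np.ndarray:
        return np.array([p.clinical_call for p in self.predict_detail(X)], dtype=object)
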