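"""Missense variants, protein metadata, and dataset-construction filters.

The pathogenic set is built from ClinVar-style records (pathogenic /
likely-pathogenic, non-somatic), the non-pathogenic set from gnomAD-style
records above an allele-frequency floor, both restricted to "pathogenic
proteins": autosomal-dominant genes carrying at least three distinct
pathogenic missense variants.  Variants claimed pathogenic but also seen in
the population set are treated as suspect and discarded from both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment import FamilyAlignment, position_to_column
from .errors import SchemaError
from .matrices import _AA_SET

logger = logging.getLogger(__name__)

INHERITANCE_MODES = ("AD", "AR", "XL", "none", "unknown")
PATHOGENIC_SIGNIFICANCE = {
    "pathogenic",
    "likely_pathogenic",
    "pathogenic/likely_pathogenic",
}

#: minimum distinct pathogenic missense variants for a protein to count as pathogenic
MIN_PATHOGENIC_VARIANTS = 3

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class MissenseVariant:
    """A single amino-acid substitution with its annotation and provenance."""

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    label: str = "unannotated"  # pathogenic | non_pathogenic | unannotated
    source: str = "user"  # clinvar | gnomad | user
    allele_frequency: float | None = None
    origin: str = "unknown"  # germline | somatic | unknown

    def __post_init__(self):
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"{self.protein_id}:{self.position} is not missense")
        if self.ref_aa not in _AA_SET or self.alt_aa not in _AA_SET:
            raise ValueError(
                f"{self.protein_id}:{self.position} non-canonical residues "
                f"{self.ref_aa}>{self.alt_aa}"
            )

    @property
    def key(self) -> VariantKey:
        return (self.protein_id, self.position, self.ref_aa, self.alt_aa)

    @property
    def hgvs_p(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class ProteinRecord:
    """Gene/protein metadata with the pathogenic-protein flag.

    ``is_pathogenic_protein`` is derived, never set independently: autosomal
    dominant inheritance AND >= 3 distinct pathogenic missense variants.
    """

    protein_id: str
    gene: str = ""
    inheritance: str = "unknown"
    n_pathogenic_missense: int = 0

    def __post_init__(self):
        if self.inheritance not in INHERITANCE_MODES:
            raise ValueError(
                f"{self.protein_id}: inheritance {self.inheritance!r} not in "
                f"{INHERITANCE_MODES}"
            )

    @property
    def is_pathogenic_protein(self) -> bool:
        return (
            self.inheritance == "AD"
            and self.n_pathogenic_missense >= MIN_PATHOGENIC_VARIANTS
        )


# ---------------------------------------------------------------------------
# Table I/O

_SCHEMAS = {
    "clinvar": [
        "protein_id",
        "position",
        "ref_aa",
        "alt_aa",
        "clinical_significance",
        "origin",
    ],
    "gnomad": ["protein_id", "position", "ref_aa", "alt_aa", "allele_frequency"],
    "user": ["protein_id", "position", "ref_aa", "alt_aa"],
}


def read_variant_table(path: str | Path, schema: str) -> list[MissenseVariant]:
    """Read a TSV of missense variants under one of the three schemas.

    Synonymous rows and rows with non-canonical residues are dropped with a
    logged count.  For the clinvar schema, only pathogenic / likely-
    pathogenic significance survives; uncertain, conflicting or benign
    records are dropped as variants with unclear consequences for this
    pipeline (the non-pathogenic set is sourced from population data, not
    from benign labels).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    return variants_from_frame(df, schema, source_name=str(path))


def variants_from_frame(
    df: pd.DataFrame, schema: str, source_name: str = "<frame>"
) -> list[MissenseVariant]:
    """Frame-level variant parser; same semantics as :func:`read_variant_table`."""
    path = source_name
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    variants: list[MissenseVariant] = []
    n_dropped_not_missense = 0
    n_dropped_significance = 0
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            position = int(row["position"])
        except (TypeError, ValueError):
            raise SchemaError(
                f"{path}: line {line_no}: unparsable position {row['position']!r}"
            )
        ref, alt = str(row["ref_aa"]).upper(), str(row["alt_aa"]).upper()
        if ref == alt or ref not in _AA_SET or alt not in _AA_SET:
            n_dropped_not_missense += 1
            continue
        label, source, af, origin = "unannotated", schema, None, "unknown"
        if schema == "clinvar":
            sig = str(row["clinical_significance"]).strip().lower().replace(" ", "_")
            if sig not in PATHOGENIC_SIGNIFICANCE:
                n_dropped_significance += 1
                continue
            label = "pathogenic"
            origin = str(row["origin"]).strip().lower()
            if origin not in ("germline", "somatic"):
                origin = "unknown"
        elif schema == "gnomad":
            label = "non_pathogenic"
            try:
                af = float(row["allele_frequency"])
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{path}: line {line_no}: unparsable allele_frequency "
                    f"{row['allele_frequency']!r}"
                )
        variants.append(
            MissenseVariant(
                protein_id=str(row["protein_id"]),
                position=position,
                ref_aa=ref,
                alt_aa=alt,
                label=label,
                source=source,
                allele_frequency=af,
                origin=origin,
            )
        )
    if n_dropped_not_missense:
        logger.info(
            "%s: dropped %d non-missense/non-canonical rows", path, n_dropped_not_missense
        )
    if n_dropped_significance:
        logger.info(
            "%s: dropped %d rows with unclear clinical significance",
            path,
            n_dropped_significance,
        )
    return variants


def write_variant_table(variants: Iterable[MissenseVariant], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "protein_id": v.protein_id,
                "position": v.position,
                "ref_aa": v.ref_aa,
                "alt_aa": v.alt_aa,
                "label": v.label,
                "source": v.source,
                "allele_frequency": v.allele_frequency,
                "origin": v.origin,
            }
            for v in variants
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_protein_table(path: str | Path) -> dict[str, ProteinRecord]:
    """Read protein metadata TSV (protein_id, gene, inheritance)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("protein_id", "inheritance") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records = {}
    for _, row in df.iterrows():
        pid = str(row["protein_id"])
        records[pid] = ProteinRecord(
            protein_id=pid,
            gene=str(row.get("gene", "") or ""),
            inheritance=str(row["inheritance"]),
        )
    return records


def write_protein_table(
    proteins: Mapping[str, ProteinRecord] | Iterable[ProteinRecord], path: str | Path
) -> None:
    records = proteins.values() if isinstance(proteins, Mapping) else proteins
    df = pd.DataFrame(
        [
            {
                "protein_id": p.protein_id,
                "gene": p.gene,
                "inheritance": p.inheritance,
                "n_pathogenic_missense": p.n_pathogenic_missense,
                "is_pathogenic_protein": p.is_pathogenic_protein,
            }
            for p in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dataset construction


def _non_somatic(v: MissenseVariant) -> bool:
    return v.origin != "somatic"


def select_pathogenic_proteins(
    proteins: Mapping[str, ProteinRecord],
    clinvar_variants: Sequence[MissenseVariant],
) -> dict[str, ProteinRecord]:
    """Count distinct pathogenic missense variants per protein and set flags.

    Proteins referenced by variants but absent from the metadata table are
    added with inheritance ``unknown`` (and a warning) so they can never be
    flagged pathogenic.
    """
    counts: dict[str, set[VariantKey]] = {}
    for v in clinvar_variants:
        if v.label == "pathogenic" and _non_somatic(v):
            counts.setdefault(v.protein_id, set()).add(v.key)

    out: dict[str, ProteinRecord] = {}
    for pid, rec in proteins.items():
        out[pid] = replace(rec, n_pathogenic_missense=len(counts.get(pid, ())))
    for pid in counts:
        if pid not in out:
            logger.warning(
                "protein %s has variants but no metadata; treating inheritance as unknown",
                pid,
            )
            out[pid] = ProteinRecord(
                protein_id=pid,
                inheritance="unknown",
                n_pathogenic_missense=len(counts[pid]),
            )
    return out


def build_datasets(
    clinvar_variants: Sequence[MissenseVariant],
    gnomad_variants: Sequence[MissenseVariant],
    proteins: Mapping[str, ProteinRecord],
    af_threshold: float = 1e-6,
) -> tuple[list[MissenseVariant], list[MissenseVariant], dict]:
    """Apply the dataset-construction filters.

    Returns (pathogenic_set, non_pathogenic_set, manifest).  The manifest
    records counts after each filter stage for provenance.
    """
    if af_threshold < 0:
        raise ValueError("af_threshold must be >= 0")
    flagged = select_pathogenic_proteins(proteins, clinvar_variants)
    pathogenic_ids = {p for p, r in flagged.items() if r.is_pathogenic_protein}

    manifest: dict = {
        "af_threshold": af_threshold,
        "n_proteins": len(flagged),
        "n_pathogenic_proteins": len(pathogenic_ids),
        "n_clinvar_in": len(clinvar_variants),
        "n_gnomad_in": len(gnomad_variants),
    }

    path_by_key: dict[VariantKey, MissenseVariant] = {}
    for v in clinvar_variants:
        if (
            v.label == "pathogenic"
            and _non_somatic(v)
            and v.protein_id in pathogenic_ids
        ):
            path_by_key.setdefault(v.key, v)
    manifest["n_pathogenic_before_intersection"] = len(path_by_key)

    nonpath_by_key: dict[VariantKey, MissenseVariant] = {}
    n_below_af = 0
    for v in gnomad_variants:
        if v.protein_id not in pathogenic_ids:
            continue
        if v.allele_frequency is None or v.allele_frequency < af_threshold:
            n_below_af += 1
            continue
        nonpath_by_key.setdefault(v.key, v)
    manifest["n_gnomad_below_af"] = n_below_af
    manifest["n_non_pathogenic_before_intersection"] = len(nonpath_by_key)

    # variants claimed pathogenic but observed in the population: drop from both
    conflict = set(path_by_key) & set(nonpath_by_key)
    manifest["n_conflicting_discarded"] = len(conflict)
    for key in conflict:
        del path_by_key[key]
        del nonpath_by_key[key]

    pathogenic_set = sorted(path_by_key.values(), key=lambda v: v.key)
    non_pathogenic_set = sorted(nonpath_by_key.values(), key=lambda v: v.key)
    manifest["n_pathogenic"] = len(pathogenic_set)
    manifest["n_non_pathogenic"] = len(non_pathogenic_set)
    return pathogenic_set, non_pathogenic_set, manifest


def domain_pathogenicity_audit(
    alignments: Sequence[FamilyAlignment],
    proteins: Mapping[str, ProteinRecord],
    pathogenic_set: Sequence[MissenseVariant],
) -> pd.DataFrame:
    """Per-family census of pathogenic vs non-pathogenic member proteins.

    Only families hosting at least one pathogenic variant (mapped into one
    of their segments) appear.  A family whose members split across both
    protein classes shows that disease association follows the protein, not
    the domain.
    """
    by_protein: dict[str, list[MissenseVariant]] = {}
    for v in pathogenic_set:
        by_protein.setdefault(v.protein_id, []).append(v)

    rows = []
    for aln in alignments:
        has_disease = False
        for seg in aln.segments:
            for v in by_protein.get(seg.protein_id, ()):
                if position_to_column(seg, v.position) is not None:
                    has_disease = True
                    break
            if has_disease:
                break
        if not has_disease:
            continue
        member_ids = {s.protein_id for s in aln.segments}
        n_path = sum(
            1
            for pid in member_ids
            if pid in proteins and proteins[pid].is_pathogenic_protein
        )
        rows.append(
            {
                "family_id": aln.family_id,
                "n_pathogenic_proteins": n_path,
                "n_non_pathogenic_proteins": len(member_ids) - n_path,
                "has_disease_variants": True,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family_id",
            "n_pathogenic_proteins",
            "n_non_pathogenic_proteins",
            "has_disease_variants",
        ],
    )
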