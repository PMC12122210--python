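"""Synthetic protein families, variant tables, and planted concordance.

Everything downstream (parsing, pair enumeration, metrics, prediction) is
testable against these generators without any database download.  A family
is grown star-wise from an unobserved root sequence: each member carries a
fixed number of substitutions so that *pairwise* member identity matches
``target_identity`` (two members at substitution rate s share roughly
(1-s)^2 + q*s^2 of their co-aligned columns, where q is the chance two
independent substitutions coincide; we invert that relation with a fixed
calibration constant q=0.13 and verify the realized identities after
generation).  Substitutions prefer BLOSUM62-positive partners with
probability 0.7 so "similar" pair categories are populated the way real
families populate them.

Variants are planted in pairs, one pair per alignment column, with a
controlled concordance rate rho: the partner copies the anchor's label
with probability rho and flips it otherwise.  Pathogenic variants go to
the ClinVar-style table, non-pathogenic ones to the gnomAD-style table
with allele frequencies in ``af_range``, and a truth table records every
planted pair for oracle tests.

What this emulates: column-equivalent substitutions with label agreement
at a known rate, identity-stratified families, AD/AR gene context.  What
it does not: phylogenetic tree structure, rate heterogeneity across sites,
indel evolution, or realistic allele-frequency spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import (
    DomainSegment,
    FamilyAlignment,
    column_to_position,
    pairwise_identity,
    residue_at_column,
)
from .errors import GenerationError
from .matrices import CANONICAL_AA, SubstitutionMatrix, load_matrix
from .variants import ProteinRecord

#: probability that a substitution lands on a BLOSUM62-positive partner
SIMILAR_SUBSTITUTION_BIAS = 0.7
#: chance two independent substitutions of one root residue coincide under
#: the biased sampler above; computed exactly from the mixture weights and
#: BLOSUM62 positive-partner set sizes, averaged over the 20 residues
_Q_COINCIDE = 0.2226
#: regeneration attempts before declaring a family spec infeasible
_MAX_ATTEMPTS = 60

#: identity tolerance checked post-generation (for domains >= this length)
IDENTITY_TOLERANCE = 0.05
IDENTITY_CHECK_MIN_LENGTH = 100


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic family."""

    n_proteins: int
    domain_length: int
    target_identity: float
    gap_rate: float = 0.05
    seed: int = 0
    family_id: str = ""

    def __post_init__(self):
        if self.n_proteins < 2:
            raise GenerationError("n_proteins must be >= 2")
        if not 0 < self.target_identity <= 1:
            raise GenerationError("target_identity must be in (0, 1]")
        if not 0 <= self.gap_rate <= 0.3:
            raise GenerationError("gap_rate must be in [0, 0.3]")


@dataclass(frozen=True)
class VariantPlantSpec:
    """Parameters of one variant-planting run."""

    n_columns_with_variants: int
    concordance_rate: float = 0.95
    pathogenic_fraction: float = 0.5
    af_range: tuple[float, float] = (1e-5, 1e-2)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.concordance_rate <= 1:
            raise GenerationError("concordance_rate must be in [0, 1]")
        if not 0 <= self.pathogenic_fraction <= 1:
            raise GenerationError("pathogenic_fraction must be in [0, 1]")
        if not 0 <= self.af_range[0] <= self.af_range[1] <= 1:
            raise GenerationError("af_range must be ordered fractions")


def _substitution_rate(target_identity: float) -> float:
    # solve (1-s)^2 + q s^2 = t  for s in [0, 1]
    q = _Q_COINCIDE
    disc = 1 - (1 + q) * (1 - target_identity)
    if disc < 0:
        raise GenerationError(
            f"target_identity {target_identity} unreachable under the "
            "substitution model"
        )
    return (1 - math.sqrt(disc)) / (1 + q)


def _draw_substitution(
    rng: np.random.Generator, residue: str, matrix: SubstitutionMatrix
) -> str:
    partners = sorted(matrix.positive_partners(residue) - {residue})
    others = [a for a in CANONICAL_AA if a != residue]
    if partners and rng.random() < SIMILAR_SUBSTITUTION_BIAS:
        return partners[rng.integers(len(partners))]
    return others[rng.integers(len(others))]


def generate_family(
    spec: FamilySpec, matrix: str | SubstitutionMatrix = "BLOSUM62"
) -> tuple[FamilyAlignment, dict[str, str]]:
    """Generate one family alignment plus full-length member sequences.

    Deterministic under ``spec.seed``.  The realized pairwise identities
    are checked post-generation (±0.05 of target, for domain_length >= 100);
    a draw violating the check is retried under a spawned sub-seed, and a
    spec that keeps failing is declared infeasible.
    """
    last_err: GenerationError | None = None
    for sub in np.random.SeedSequence(spec.seed).spawn(_MAX_ATTEMPTS):
        try:
            return _generate_family_once(spec, sub, matrix)
        except GenerationError as err:
            last_err = err
    raise GenerationError(
        f"family spec infeasible after {_MAX_ATTEMPTS} attempts: {last_err}"
    )


def _generate_family_once(
    spec: FamilySpec,
    seed_seq: np.random.SeedSequence,
    matrix: str | SubstitutionMatrix = "BLOSUM62",
) -> tuple[FamilyAlignment, dict[str, str]]:
    m = load_matrix(matrix) if isinstance(matrix, str) else matrix
    rng_root, rng_members, rng_embed = (
        np.random.default_rng(s) for s in seed_seq.spawn(3)
    )
    family_id = spec.family_id or f"SYNF{spec.seed % 100000:05d}"
    L = spec.domain_length
    root = "".join(CANONICAL_AA[i] for i in rng_root.integers(0, 20, size=L))
    s = _substitution_rate(spec.target_identity)
    n_sub = int(round(s * L))
    n_gap = int(round(spec.gap_rate * L))
    if L - n_gap < 1:
        raise GenerationError("gap_rate leaves no residues")

    segments = []
    full_seqs: dict[str, str] = {}
    for i in range(spec.n_proteins):
        pid = f"{family_id}_P{i + 1:03d}"
        chars = list(root)
        for j in rng_members.choice(L, size=n_sub, replace=False):
            chars[j] = _draw_substitution(rng_members, chars[j], m)
        for j in rng_members.choice(L, size=n_gap, replace=False):
            chars[j] = "-"
        aligned = "".join(chars)
        residues = aligned.replace("-", "")
        seg_start = int(rng_embed.integers(1, 41))
        left = "".join(
            CANONICAL_AA[k] for k in rng_embed.integers(0, 20, size=seg_start - 1)
        )
        right = "".join(
            CANONICAL_AA[k] for k in rng_embed.integers(0, 20, size=int(rng_embed.integers(0, 31)))
        )
        full_seqs[pid] = left + residues + right
        segments.append(
            DomainSegment(
                protein_id=pid,
                family_id=family_id,
                seg_start=seg_start,
                seg_end=seg_start + len(residues) - 1,
                aligned_seq=aligned,
            )
        )
    aln = FamilyAlignment.from_segments(family_id, segments)

    if L >= IDENTITY_CHECK_MIN_LENGTH:
        for a_idx in range(len(segments)):
            for b_idx in range(a_idx + 1, len(segments)):
                ident = pairwise_identity(segments[a_idx], segments[b_idx])
                if ident is None or abs(ident - spec.target_identity) > IDENTITY_TOLERANCE:
                    raise GenerationError(
                        f"{family_id}: realized identity {ident} strays from "
                        f"target {spec.target_identity} by more than "
                        f"{IDENTITY_TOLERANCE}"
                    )
    return aln, full_seqs


def make_protein_table(
    alignments: Sequence[FamilyAlignment] | FamilyAlignment,
    inheritance: str = "AD",
    seed: int | None = None,
    inheritance_choices: Sequence[str] = ("AD", "AR", "XL", "none"),
    ad_fraction: float | None = None,
) -> dict[str, ProteinRecord]:
    """Protein metadata for all alignment members.

    With ``ad_fraction`` set, inheritance is drawn randomly (AD with that
    probability, else uniformly among the remaining modes); otherwise every
    member gets ``inheritance``.
    """
    if isinstance(alignments, FamilyAlignment):
        alignments = [alignments]
    rng = np.random.default_rng(seed)
    records: dict[str, ProteinRecord] = {}
    for aln in alignments:
        for seg in aln.segments:
            if seg.protein_id in records:
                continue
            if ad_fraction is None:
                mode = inheritance
            elif rng.random() < ad_fraction:
                mode = "AD"
            else:
                rest = [c for c in inheritance_choices if c != "AD"]
                mode = rest[rng.integers(len(rest))]
            records[seg.protein_id] = ProteinRecord(
                protein_id=seg.protein_id, gene=seg.protein_id, inheritance=mode
            )
    return records


def plant_variants(
    alignment: FamilyAlignment,
    plant: VariantPlantSpec,
    proteins: Mapping[str, ProteinRecord] | None = None,
    matrix: str | SubstitutionMatrix = "BLOSUM62",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plant one homologous variant pair per chosen column.

    Returns (clinvar_table, gnomad_table, truth_table) as DataFrames in the
    package's TSV schemas.  Only columns offering two distinct proteins
    with identical or BLOSUM-similar residues are eligible, so every
    planted pair is recoverable by pair enumeration; the anchor's label is
    pathogenic with probability ``pathogenic_fraction`` and the partner
    agrees with probability ``concordance_rate``.
    """
    m = load_matrix(matrix) if isinstance(matrix, str) else matrix
    rng = np.random.default_rng(np.random.SeedSequence(plant.seed))

    eligible: list[tuple[int, list[tuple]]] = []
    for col in range(1, alignment.n_columns + 1):
        carriers = [
            (seg, residue_at_column(seg, col))
            for seg in alignment.segments
            if residue_at_column(seg, col) is not None
        ]
        pairs = [
            (sa, ra, sb, rb)
            for i, (sa, ra) in enumerate(carriers)
            for sb, rb in carriers[i + 1 :]
            if sa.protein_id != sb.protein_id and m.similar(ra, rb)
        ]
        if pairs:
            eligible.append((col, pairs))
    if plant.n_columns_with_variants > len(eligible):
        raise GenerationError(
            f"requested {plant.n_columns_with_variants} variant columns but only "
            f"{len(eligible)} columns have a similar-residue protein pair"
        )
    chosen_idx = rng.choice(len(eligible), size=plant.n_columns_with_variants, replace=False)

    clinvar_rows, gnomad_rows, truth_rows = [], [], []

    def emit(pid: str, pos: int, ref: str, alt: str, label: str) -> None:
        if label == "pathogenic":
            clinvar_rows.append(
                {
                    "protein_id": pid,
                    "position": pos,
                    "ref_aa": ref,
                    "alt_aa": alt,
                    "clinical_significance": "pathogenic",
                    "origin": "germline",
                }
            )
        else:
            af = float(rng.uniform(plant.af_range[0], plant.af_range[1]))
            gnomad_rows.append(
                {
                    "protein_id": pid,
                    "position": pos,
                    "ref_aa": ref,
                    "alt_aa": alt,
                    "allele_frequency": af,
                }
            )

    for ci in sorted(chosen_idx):
        col, pairs = eligible[ci]
        seg_a, ref_a, seg_b, ref_b = pairs[rng.integers(len(pairs))]
        # anchor alternate: prefer a similar residue, as real substitutions do
        alt_a = _draw_substitution(rng, ref_a, m)
        # partner alternate must keep the pair enumerable: similar to alt_a
        alt_b = None
        for _ in range(20):
            candidates = sorted(m.positive_partners(alt_a) - {ref_b})
            if candidates:
                alt_b = alt_a if alt_a in candidates and rng.random() < 0.5 else (
                    candidates[rng.integers(len(candidates))]
                )
                break
            alt_a = _draw_substitution(rng, ref_a, m)
        if alt_b is None:  # pragma: no cover - positive partners always exist
            continue
        label_a = (
            "pathogenic"
            if rng.random() < plant.pathogenic_fraction
            else "non_pathogenic"
        )
        concordant = bool(rng.random() < plant.concordance_rate)
        label_b = (
            label_a
            if concordant
            else ("non_pathogenic" if label_a == "pathogenic" else "pathogenic")
        )
        pos_a = column_to_position(seg_a, col)
        pos_b = column_to_position(seg_b, col)
        emit(seg_a.protein_id, pos_a, ref_a, alt_a, label_a)
        emit(seg_b.protein_id, pos_b, ref_b, alt_b, label_b)
        truth_rows.append(
            {
                "family_id": alignment.family_id,
                "column": col,
                "protein_a": seg_a.protein_id,
                "position_a": pos_a,
                "ref_a": ref_a,
                "alt_a": alt_a,
                "label_a": label_a,
                "protein_b": seg_b.protein_id,
                "position_b": pos_b,
                "ref_b": ref_b,
                "alt_b": alt_b,
                "label_b": label_b,
                "concordant": concordant,
            }
        )

    clinvar_df = pd.DataFrame(
        clinvar_rows,
        columns=[
            "protein_id",
            "position",
            "ref_aa",
            "alt_aa",
            "clinical_significance",
            "origin",
        ],
    )
    gnomad_df = pd.DataFrame(
        gnomad_rows,
        columns=["protein_id", "position", "ref_aa", "alt_aa", "allele_frequency"],
    )
    truth_df = pd.DataFrame(truth_rows)
    return clinvar_df, gnomad_df, truth_df


def generate_benchmark(
    n_families: int = 10,
    n_proteins: int = 8,
    domain_length: int = 220,
    target_identity: float = 0.6,
    columns_per_family: int = 150,
    concordance_rate: float = 0.95,
    pathogenic_fraction: float = 0.5,
    gap_rate: float = 0.05,
    seed: int = 0,
    family_prefix: str = "SYNF",
) -> dict:
    """Generate a multi-family planted benchmark.

    Returns a dict with alignments, proteins (all AD), the clinvar/gnomad
    tables (concatenated across families) and the truth table.  Intended
    as the backbone for parameter-recovery experiments: with one planted
    pair per column, the fraction of concordant enumerated pairs estimates
    ``concordance_rate`` directly.
    """
    fam_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n_families)]
    alignments, clinvar_parts, gnomad_parts, truth_parts = [], [], [], []
    proteins: dict[str, ProteinRecord] = {}
    for i, fs in enumerate(fam_seeds):
        spec = FamilySpec(
            n_proteins=n_proteins,
            domain_length=domain_length,
            target_identity=target_identity,
            gap_rate=gap_rate,
            seed=fs,
            family_id=f"{family_prefix}{i + 1:04d}",
        )
        aln, _ = generate_family(spec)
        alignments.append(aln)
        proteins.update(make_protein_table(aln, inheritance="AD"))
        plant = VariantPlantSpec(
            n_columns_with_variants=columns_per_family,
            concordance_rate=concordance_rate,
            pathogenic_fraction=pathogenic_fraction,
            seed=fs + 1,
        )
        cv, gn, tr = plant_variants(aln, plant, proteins)
        clinvar_parts.append(cv)
        gnomad_parts.append(gn)
        truth_parts.append(tr)
    return {
        "alignments": alignments,
        "proteins": proteins,
        "clinvar": pd.concat(clinvar_parts, ignore_index=True),
        "gnomad": pd.concat(gnomad_parts, ignore_index=True),
        "truth": pd.concat(truth_parts, ignore_index=True),
    }
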