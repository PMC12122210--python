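"""Family alignments and residue/column coordinate mapping.

The unit of homology here is the *domain segment*: one protein's aligned
subsequence within a family multiple sequence alignment, with its residue
span given by the ``name/start-end`` header convention (1-based inclusive,
as in protein coordinates).  Columns are 1-based.  Both ``-`` and ``.`` are
gaps and are never distinguished; lowercase (insert-state) residues are
uppercased.

The Stockholm reader is deliberately strict: it validates that each row's
residue count matches its declared span and reports errors with line
numbers, which generic alignment readers do not surface.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import (
    AlignmentStructureError,
    ContentError,
    StockholmParseError,
)
from .matrices import _AA_SET

GAP_CHARS = frozenset("-.")
_HEADER_RE = re.compile(r"^(?P<name>\S+)/(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class DomainSegment:
    """One protein's aligned domain subsequence.

    ``seg_start``/``seg_end`` are 1-based inclusive residue coordinates in
    the full protein; the number of non-gap characters in ``aligned_seq``
    must equal the span length.
    """

    protein_id: str
    family_id: str
    seg_start: int
    seg_end: int
    aligned_seq: str

    def __post_init__(self):
        if self.seg_start < 1:
            raise AlignmentStructureError(
                f"{self.protein_id}: seg_start must be >= 1, got {self.seg_start}"
            )
        if self.seg_start > self.seg_end:
            raise AlignmentStructureError(
                f"{self.protein_id}: seg_start {self.seg_start} > seg_end {self.seg_end}"
            )
        bad = set(self.aligned_seq) - _AA_SET - GAP_CHARS
        if bad:
            raise ContentError(
                f"{self.protein_id}: non-residue, non-gap characters {sorted(bad)!r}"
            )
        span = self.seg_end - self.seg_start + 1
        n_res = self.n_residues
        if n_res != span:
            raise AlignmentStructureError(
                f"{self.protein_id}/{self.seg_start}-{self.seg_end}: "
                f"{n_res} residues in aligned sequence but span covers {span}"
            )

    @property
    def n_residues(self) -> int:
        return sum(1 for c in self.aligned_seq if c not in GAP_CHARS)

    @property
    def name(self) -> str:
        return f"{self.protein_id}/{self.seg_start}-{self.seg_end}"


@dataclass(frozen=True)
class FamilyAlignment:
    """An aligned protein family: >=1 domain segments of equal aligned length."""

    family_id: str
    segments: tuple[DomainSegment, ...]
    n_columns: int

    @classmethod
    def from_segments(
        cls, family_id: str, segments: Sequence[DomainSegment]
    ) -> "FamilyAlignment":
        segments = tuple(segments)
        if not segments:
            raise AlignmentStructureError(f"{family_id}: empty alignment")
        n_cols = len(segments[0].aligned_seq)
        for seg in segments:
            if len(seg.aligned_seq) != n_cols:
                raise AlignmentStructureError(
                    f"{family_id}: {seg.name} has aligned length "
                    f"{len(seg.aligned_seq)}, expected {n_cols}"
                )
        keys = [(s.protein_id, s.seg_start) for s in segments]
        if len(set(keys)) != len(keys):
            raise AlignmentStructureError(
                f"{family_id}: duplicate (protein, seg_start) rows"
            )
        return cls(family_id, segments, n_cols)

    def segments_for(self, protein_id: str) -> tuple[DomainSegment, ...]:
        return tuple(s for s in self.segments if s.protein_id == protein_id)


def position_to_column(seg: DomainSegment, pos: int) -> int | None:
    """1-based alignment column holding residue ``pos``; None outside the span."""
    if pos < seg.seg_start or pos > seg.seg_end:
        return None
    target = pos - seg.seg_start + 1  # ordinal of the residue within the segment
    seen = 0
    for i, c in enumerate(seg.aligned_seq, start=1):
        if c not in GAP_CHARS:
            seen += 1
            if seen == target:
                return i
    raise AlignmentStructureError(f"{seg.name}: ran out of residues")  # unreachable


def column_to_position(seg: DomainSegment, col: int) -> int | None:
    """Residue coordinate at alignment column ``col``; None if the column is a gap."""
    if col < 1 or col > len(seg.aligned_seq):
        raise IndexError(
            f"column {col} out of range 1..{len(seg.aligned_seq)} for {seg.name}"
        )
    if seg.aligned_seq[col - 1] in GAP_CHARS:
        return None
    n_before = sum(1 for c in seg.aligned_seq[: col - 1] if c not in GAP_CHARS)
    return seg.seg_start + n_before


def residue_at_column(seg: DomainSegment, col: int) -> str | None:
    """Residue character at ``col``, or None for a gap."""
    if col < 1 or col > len(seg.aligned_seq):
        raise IndexError(f"column {col} out of range for {seg.name}")
    c = seg.aligned_seq[col - 1]
    return None if c in GAP_CHARS else c


#: identity denominator policies: co-aligned columns (default), full
#: alignment length, or the mean of the two segments' residue counts
IDENTITY_DENOMINATORS = ("coaligned", "alignment_length", "mean_length")


def pairwise_identity(
    seg_a: DomainSegment,
    seg_b: DomainSegment,
    denominator: str = "coaligned",
) -> float | None:
    """Fraction of identical residues between two aligned segments.

    With the default ``coaligned`` policy the denominator is the number of
    columns where both segments carry a residue, so one-sided gaps are not
    penalized; ``alignment_length`` divides by every column and
    ``mean_length`` by the average residue count.  Returns None when the
    denominator is zero.
    """
    if len(seg_a.aligned_seq) != len(seg_b.aligned_seq):
        raise AlignmentStructureError(
            f"{seg_a.name} and {seg_b.name} have different aligned lengths"
        )
    if denominator not in IDENTITY_DENOMINATORS:
        raise ValueError(
            f"unknown denominator {denominator!r}; choose from {IDENTITY_DENOMINATORS}"
        )
    both = 0
    same = 0
    for ca, cb in zip(seg_a.aligned_seq, seg_b.aligned_seq):
        if ca in GAP_CHARS or cb in GAP_CHARS:
            continue
        both += 1
        if ca == cb:
            same += 1
    if denominator == "alignment_length":
        den: float = len(seg_a.aligned_seq)
    elif denominator == "mean_length":
        den = (seg_a.n_residues + seg_b.n_residues) / 2
    else:
        den = both
    if den == 0:
        return None
    return same / den


# ---------------------------------------------------------------------------
# Stockholm 1.0 I/O


def _parse_seq_header(token: str, line_no: int) -> tuple[str, int, int]:
    m = _HEADER_RE.match(token)
    if not m:
        raise StockholmParseError(
            f"sequence name {token!r} is not of the form name/start-end", line_no
        )
    return m.group("name"), int(m.group("start")), int(m.group("end"))


def parse_stockholm(text: str) -> list[FamilyAlignment]:
    """Parse one or more Stockholm 1.0 records into family alignments.

    Handles interleaved blocks (same-name lines concatenated), reads the
    family id from ``#=GF AC`` (version suffix stripped) or ``#=GF ID``,
    uppercases residues and treats ``.`` and ``-`` as gaps.
    """
    alignments: list[FamilyAlignment] = []
    rows: dict[str, list[str]] = {}
    header_lines: dict[str, int] = {}
    order: list[str] = []
    gf_ac: str | None = None
    gf_id: str | None = None
    in_record = False

    def finalize():
        nonlocal rows, order, gf_ac, gf_id, in_record
        if not order:
            rows, gf_ac, gf_id, in_record = {}, None, None, False
            return
        family_id = gf_ac or gf_id or f"family{len(alignments) + 1}"
        segments = []
        for token in order:
            name, start, end = _parse_seq_header(token, header_lines[token])
            seq = "".join(rows[token]).upper()
            segments.append(
                DomainSegment(
                    protein_id=name,
                    family_id=family_id,
                    seg_start=start,
                    seg_end=end,
                    aligned_seq=seq,
                )
            )
        alignments.append(FamilyAlignment.from_segments(family_id, segments))
        rows, order, gf_ac, gf_id, in_record = {}, [], None, None, False

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith("# STOCKHOLM"):
            if in_record:
                raise StockholmParseError("record not terminated by //", line_no)
            in_record = True
            continue
        if line == "//":
            if not in_record:
                raise StockholmParseError("// outside a record", line_no)
            finalize()
            continue
        if line.startswith("#=GF"):
            parts = line.split(None, 2)
            if len(parts) == 3:
                _, feat, value = parts
                if feat == "AC" and gf_ac is None:
                    gf_ac = value.split(".")[0]
                elif feat == "ID" and gf_id is None:
                    gf_id = value
            continue
        if line.startswith("#"):
            continue  # GS/GR/GC annotations are not used
        parts = line.split()
        if len(parts) != 2:
            raise StockholmParseError(
                f"expected 'name/start-end sequence', got {line!r}", line_no
            )
        token, seq = parts
        _parse_seq_header(token, line_no)  # fail early with the line number
        bad = set(seq.upper()) - _AA_SET - GAP_CHARS
        if bad:
            raise ContentError(
                f"line {line_no}: invalid characters {sorted(bad)!r} in {token}"
            )
        if token not in rows:
            rows[token] = []
            order.append(token)
            header_lines[token] = line_no
        rows[token].append(seq)

    if in_record:
        raise StockholmParseError("file ended inside an unterminated record")
    return alignments


def write_stockholm(alignments: Iterable[FamilyAlignment]) -> str:
    """Serialize alignments as single-block Stockholm 1.0 records."""
    out = []
    for aln in alignments:
        out.append("# STOCKHOLM 1.0")
        out.append(f"#=GF ID {aln.family_id}")
        out.append(f"#=GF AC {aln.family_id}")
        width = max(len(s.name) for s in aln.segments)
        for seg in aln.segments:
            out.append(f"{seg.name:<{width}}  {seg.aligned_seq}")
        out.append("//")
    return "\n".join(out) + "\n"


def parse_gapped_fasta(text: str, family_id: str) -> FamilyAlignment:
    """Read an aligned (gapped) FASTA with ``>name/start-end`` headers."""
    segments = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        name, start, end = _parse_seq_header(rec.id, 0)
        segments.append(
            DomainSegment(
                protein_id=name,
                family_id=family_id,
                seg_start=start,
                seg_end=end,
                aligned_seq=str(rec.seq).upper(),
            )
        )
    return FamilyAlignment.from_segments(family_id, segments)
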