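"""Independent oracles used by unit and acceptance tests.

These deliberately re-derive column mapping and similarity flags through
the public per-segment primitives, never through the production
column-index enumeration path they are checking.
"""

from itertools import combinations

from varhomol import load_matrix, pairwise_identity, position_to_column


def brute_force_pairs(alignments, variants, matrix="BLOSUM62"):
    """O(n^2)-over-all-variant-pairs oracle for homologous pair enumeration.

    Returns {frozenset((key_a, key_b)): (family_id, identity, column)} with
    the highest-identity occurrence kept, mirroring the dedup contract.
    """
    m = load_matrix(matrix)
    found = {}
    for va, vb in combinations(variants, 2):
        if va.protein_id == vb.protein_id:
            continue
        for aln in alignments:
            for seg_a in aln.segments_for(va.protein_id):
                col_a = position_to_column(seg_a, va.position)
                if col_a is None or seg_a.aligned_seq[col_a - 1] != va.ref_aa:
                    continue
                for seg_b in aln.segments_for(vb.protein_id):
                    col_b = position_to_column(seg_b, vb.position)
                    if col_b is None or seg_b.aligned_seq[col_b - 1] != vb.ref_aa:
                        continue
                    if col_a != col_b:
                        continue
                    if not (
                        m.similar(va.ref_aa, vb.ref_aa)
                        and m.similar(va.alt_aa, vb.alt_aa)
                    ):
                        continue
                    ident = pairwise_identity(seg_a, seg_b)
                    key = frozenset((va.key, vb.key))
                    prev = found.get(key)
                    if prev is None or ident > prev[1]:
                        found[key] = (aln.family_id, ident, col_a)
    return found
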