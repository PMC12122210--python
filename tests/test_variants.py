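"""Variant table parsing and the dataset-construction filters."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varhomol import (
    DomainSegment,
    FamilyAlignment,
    MissenseVariant,
    ProteinRecord,
    build_datasets,
    domain_pathogenicity_audit,
    select_pathogenic_proteins,
    variants_from_frame,
)
from varhomol.errors import SchemaError


def clinvar_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "position",
            "ref_aa",
            "alt_aa",
            "clinical_significance",
            "origin",
        ],
    )


def gnomad_frame(rows):
    return pd.DataFrame(
        rows, columns=["protein_id", "position", "ref_aa", "alt_aa", "allele_frequency"]
    )


class TestReadVariantTable:
    def test_pathogenic_label_mapping(self):
        df = clinvar_frame([("P1", 440, "N", "K", "pathogenic", "germline")])
        (v,) = variants_from_frame(df, "clinvar")
        assert v.label == "pathogenic"
        assert v.hgvs_p == "p.N440K"

    @pytest.mark.parametrize(
        "significance, kept",
        [
            ("pathogenic", True),
            ("likely_pathogenic", True),
            ("Pathogenic/Likely_pathogenic", True),
            ("uncertain_significance", False),
            ("conflicting_interpretations", False),
            ("benign", False),
        ],
    )
    def test_unclear_consequences_dropped(self, significance, kept):
        df = clinvar_frame([("P1", 10, "A", "V", significance, "germline")])
        out = variants_from_frame(df, "clinvar")
        assert bool(out) is kept

    def test_synonymous_and_noncanonical_dropped(self):
        df = clinvar_frame(
            [
                ("P1", 10, "A", "A", "pathogenic", "germline"),
                ("P1", 11, "X", "V", "pathogenic", "germline"),
                ("P1", 12, "A", "*", "pathogenic", "germline"),
            ]
        )
        assert variants_from_frame(df, "clinvar") == []

    def test_missing_column_is_schema_error(self):
        df = clinvar_frame([("P1", 10, "A", "V", "pathogenic", "germline")]).drop(
            columns=["origin"]
        )
        with pytest.raises(SchemaError, match="origin"):
            variants_from_frame(df, "clinvar")

    def test_unparsable_position_is_row_error(self):
        df = gnomad_frame([("P1", "ten", "A", "V", 1e-4)])
        with pytest.raises(SchemaError, match="position"):
            variants_from_frame(df, "gnomad")

    def test_gnomad_gets_allele_frequency(self):
        df = gnomad_frame([("P1", 10, "A", "V", "0.0001")])
        (v,) = variants_from_frame(df, "gnomad")
        assert v.label == "non_pathogenic"
        assert v.allele_frequency == pytest.approx(1e-4)


class TestPathogenicProteins:
    @pytest.mark.parametrize(
        "inheritance, n_variants, flagged",
        [("AD", 3, True), ("AD", 2, False), ("AR", 50, False), ("AD", 0, False)],
    )
    def test_flag_rule(self, inheritance, n_variants, flagged):
        proteins = {"P1": ProteinRecord("P1", inheritance=inheritance)}
        variants = [
            MissenseVariant("P1", 10 + i, "A", "V", label="pathogenic",
                            source="clinvar", origin="germline")
            for i in range(n_variants)
        ]
        out = select_pathogenic_proteins(proteins, variants)
        assert out["P1"].is_pathogenic_protein is flagged
        assert out["P1"].n_pathogenic_missense == n_variants

    def test_duplicate_variants_counted_once(self):
        proteins = {"P1": ProteinRecord("P1", inheritance="AD")}
        v = MissenseVariant("P1", 10, "A", "V", label="pathogenic",
                            source="clinvar", origin="germline")
        out = select_pathogenic_proteins(proteins, [v, v, v, v])
        assert out["P1"].n_pathogenic_missense == 1
        assert not out["P1"].is_pathogenic_protein

    def test_somatic_variants_do_not_count(self):
        proteins = {"P1": ProteinRecord("P1", inheritance="AD")}
        variants = [
            MissenseVariant("P1", 10 + i, "A", "V", label="pathogenic",
                            source="clinvar", origin="somatic")
            for i in range(5)
        ]
        out = select_pathogenic_proteins(proteins, variants)
        assert not out["P1"].is_pathogenic_protein

    def test_unknown_protein_gets_unknown_inheritance(self):
        variants = [
            MissenseVariant("P9", 10, "A", "V", label="pathogenic",
                            source="clinvar", origin="germline")
        ]
        out = select_pathogenic_proteins({}, variants)
        assert out["P9"].inheritance == "unknown"
        assert not out["P9"].is_pathogenic_protein


def _ad_protein_with_variants(pid="P1", n=3, start=10):
    variants = [
        MissenseVariant(pid, start + i, "A", "V", label="pathogenic",
                        source="clinvar", origin="germline")
        for i in range(n)
    ]
    return {pid: ProteinRecord(pid, inheritance="AD")}, variants


class TestBuildDatasets:
    def test_af_floor_excludes_rare(self):
        proteins, cv = _ad_protein_with_variants()
        gn = [
            MissenseVariant("P1", 50, "G", "R", label="non_pathogenic",
                            source="gnomad", allele_frequency=5e-7),
            MissenseVariant("P1", 51, "G", "R", label="non_pathogenic",
                            source="gnomad", allele_frequency=1e-6),
        ]
        _, nonpath, _ = build_datasets(cv, gn, proteins, af_threshold=1e-6)
        assert [v.position for v in nonpath] == [51]  # keep at exactly the floor

    def test_conflicting_variant_dropped_from_both(self):
        proteins, cv = _ad_protein_with_variants(n=4)
        shadow = MissenseVariant("P1", 10, "A", "V", label="non_pathogenic",
                                 source="gnomad", allele_frequency=1e-4)
        path, nonpath, manifest = build_datasets(cv, [shadow], proteins)
        keys = {v.key for v in path} | {v.key for v in nonpath}
        assert ("P1", 10, "A", "V") not in keys
        assert manifest["n_conflicting_discarded"] == 1

    def test_zero_threshold_keeps_everything_nonconflicting(self):
        proteins, cv = _ad_protein_with_variants()
        gn = [
            MissenseVariant("P1", 60 + i, "G", "R", label="non_pathogenic",
                            source="gnomad", allele_frequency=af)
            for i, af in enumerate([1e-9, 0.5, 1e-3])
        ]
        _, nonpath, _ = build_datasets(cv, gn, proteins, af_threshold=0.0)
        assert len(nonpath) == 3

    def test_non_flagged_protein_excluded_entirely(self):
        proteins = {"P1": ProteinRecord("P1", inheritance="AR")}
        cv = [
            MissenseVariant("P1", 10 + i, "A", "V", label="pathogenic",
                            source="clinvar", origin="germline")
            for i in range(5)
        ]
        gn = [MissenseVariant("P1", 50, "G", "R", label="non_pathogenic",
                              source="gnomad", allele_frequency=1e-3)]
        path, nonpath, _ = build_datasets(cv, gn, proteins)
        assert path == [] and nonpath == []

    @settings(deadline=None, max_examples=25)
    @given(st.data())
    def test_invariants_on_random_inputs(self, data):
        """Output sets are disjoint, live on flagged proteins, and the
        non-pathogenic set shrinks monotonically with the AF floor."""
        proteins = {
            f"P{i}": ProteinRecord(f"P{i}", inheritance=data.draw(st.sampled_from(["AD", "AR"])))
            for i in range(3)
        }
        cv = [
            MissenseVariant(
                f"P{data.draw(st.integers(0, 2))}",
                data.draw(st.integers(1, 30)),
                "A",
                "V",
                label="pathogenic",
                source="clinvar",
                origin=data.draw(st.sampled_from(["germline", "somatic"])),
            )
            for _ in range(data.draw(st.integers(0, 12)))
        ]
        gn = [
            MissenseVariant(
                f"P{data.draw(st.integers(0, 2))}",
                data.draw(st.integers(1, 30)),
                "A",
                "V",
                label="non_pathogenic",
                source="gnomad",
                allele_frequency=data.draw(st.floats(0, 1e-3)),
            )
            for _ in range(data.draw(st.integers(0, 12)))
        ]
        flagged = select_pathogenic_proteins(proteins, cv)
        lo, hi = sorted(
            [data.draw(st.floats(0, 1e-4)), data.draw(st.floats(0, 1e-4))]
        )
        path_lo, non_lo, _ = build_datasets(cv, gn, proteins, af_threshold=lo)
        path_hi, non_hi, _ = build_datasets(cv, gn, proteins, af_threshold=hi)
        assert {v.key for v in path_lo}.isdisjoint({v.key for v in non_lo})
        assert len(non_hi) <= len(non_lo)
        for v in path_lo + non_lo:
            assert flagged[v.protein_id].is_pathogenic_protein


class TestDomainAudit:
    def _family(self):
        segs = [
            DomainSegment("P1", "PF1", 1, 4, "ACDE"),
            DomainSegment("P2", "PF1", 1, 4, "ACDD"),
        ]
        return FamilyAlignment.from_segments("PF1", segs)

    def test_counts_members_by_flag(self):
        aln = self._family()
        proteins = {
            "P1": ProteinRecord("P1", inheritance="AD", n_pathogenic_missense=3),
            "P2": ProteinRecord("P2", inheritance="AR", n_pathogenic_missense=0),
        }
        path = [MissenseVariant("P1", 2, "C", "R", label="pathogenic")]
        table = domain_pathogenicity_audit([aln], proteins, path)
        row = table.iloc[0]
        assert (row.n_pathogenic_proteins, row.n_non_pathogenic_proteins) == (1, 1)
        assert bool(row.has_disease_variants)

    def test_family_without_pathogenic_variants_excluded(self):
        aln = self._family()
        proteins = {"P1": ProteinRecord("P1", inheritance="AD", n_pathogenic_missense=3)}
        table = domain_pathogenicity_audit([aln], proteins, [])
        assert table.empty

    def test_mixed_membership_census(self):
        """A domain hosted by 14 pathogenic and 9 non-pathogenic proteins."""
        segs = [
            DomainSegment(f"P{i:02d}", "PF520", 1, 3, "NKD") for i in range(23)
        ]
        aln = FamilyAlignment.from_segments("PF520", segs)
        proteins = {}
        for i in range(23):
            mode = "AD" if i < 14 else "AR"
            n = 3 if i < 14 else 0
            proteins[f"P{i:02d}"] = ProteinRecord(
                f"P{i:02d}", inheritance=mode, n_pathogenic_missense=n
            )
        path = [MissenseVariant("P00", 1, "N", "K", label="pathogenic")]
        row = domain_pathogenicity_audit([aln], proteins, path).iloc[0]
        assert (row.n_pathogenic_proteins, row.n_non_pathogenic_proteins) == (14, 9)
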