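import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

from varhomol import (  # noqa: E402
    DomainSegment,
    FamilyAlignment,
    MissenseVariant,
    ProteinRecord,
)


@pytest.fixture
def seg():
    """Five-column segment with one gap: residues A,C,D,E at positions 10-13."""
    return DomainSegment(
        protein_id="A_HUMAN",
        family_id="PF99901",
        seg_start=10,
        seg_end=13,
        aligned_seq="AC-DE",
    )


@pytest.fixture
def channel_family():
    """Two sodium-channel-like segments sharing an N at column 3.

    Mimics paralogous pore-region domains: position 440 of the first
    protein and position 406 of the second co-align.
    """
    seg4a = DomainSegment(
        protein_id="SCN4A",
        family_id="PF00520",
        seg_start=438,
        seg_end=442,
        aligned_seq="QWNDE",
    )
    seg5a = DomainSegment(
        protein_id="SCN5A",
        family_id="PF00520",
        seg_start=404,
        seg_end=408,
        aligned_seq="QWNDL",
    )
    return FamilyAlignment.from_segments("PF00520", (seg4a, seg5a))


@pytest.fixture
def channel_variants():
    va = MissenseVariant("SCN4A", 440, "N", "K", label="pathogenic", source="clinvar", origin="germline")
    vb = MissenseVariant("SCN5A", 406, "N", "K", label="pathogenic", source="clinvar", origin="germline")
    return va, vb


@pytest.fixture
def ad_protein():
    return ProteinRecord("SCN4A", gene="SCN4A", inheritance="AD", n_pathogenic_missense=5)


@pytest.fixture
def ar_protein():
    return ProteinRecord("SCN4A", gene="SCN4A", inheritance="AR", n_pathogenic_missense=5)
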