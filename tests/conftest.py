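import pytest

from rarearch.model import (
    AnnotatedVariant,
    ConsequenceClass,
    GenotypeCall,
    Group,
    Proband,
    Sex,
    Verdict,
    Zygosity,
)
from rarearch.panel_io import default_panel


@pytest.fixture
def panel():
    return default_panel()


def make_variant(
    variant_id="chr8:1000:A:G",
    gene="FGFR1",
    raw="missense_variant",
    maf=0.0,
    population="NFE",
    predictor_a=Verdict.DAMAGING,
    predictor_b=Verdict.TOLERATED,
    invitro=False,
    consequence=None,
    boundary=None,
):
    v = AnnotatedVariant(
        variant_id=variant_id,
        gene_symbol=gene,
        raw_consequence=raw,
        reference_maf={population: maf},
        predictor_a=predictor_a,
        predictor_b=predictor_b,
        invitro_lof=invitro,
        exon_boundary_distance=boundary,
    )
    if consequence is not None:
        v.consequence_class = consequence
    return v


def make_call(proband="P1", variant_id="chr8:1000:A:G", zygosity=Zygosity.HET, gq=99.0):
    return GenotypeCall(proband, variant_id, zygosity, gq)


def make_proband(pid="P1", group=Group.KS, sex=Sex.MALE):
    return Proband(pid, group, sex)


@pytest.fixture
def small_cohort(panel):
    """Six probands: two oligogenic, one biallelic, one hemizygous carrier,
    one monogenic, one non-carrier."""
    probands = [
        make_proband("K1", Group.KS),
        make_proband("K2", Group.KS),
        make_proband("N1", Group.NCHH, Sex.FEMALE),
        make_proband("N2", Group.NCHH),
        make_proband("C1", Group.CDGP),
        make_proband("C2", Group.CDGP, Sex.FEMALE),
    ]
    variants = [
        make_variant("chr8:1:A:G", "FGFR1", "missense_variant"),
        make_variant("chr8:2:C:T", "CHD7", "stop_gained"),
        make_variant("chr4:3:G:A", "GNRHR", "missense_variant"),
        make_variant("chr4:4:T:C", "GNRHR", "missense_variant"),
        make_variant("chrX:5:A:C", "ANOS1", "frameshift_variant"),
        make_variant("chr8:6:G:C", "FGFR1", "missense_variant"),
        make_variant("chr9:7:A:T", "CHD7", "missense_variant"),
    ]
    calls = [
        # K1: oligogenic (FGFR1 + CHD7)
        make_call("K1", "chr8:1:A:G"),
        make_call("K1", "chr8:2:C:T"),
        # K2: hemizygous ANOS1, monogenic
        GenotypeCall("K2", "chrX:5:A:C", Zygosity.HEMI, 99.0),
        # N1: compound het GNRHR -> biallelic, monogenic
        make_call("N1", "chr4:3:G:A"),
        make_call("N1", "chr4:4:T:C"),
        # N2: oligogenic (FGFR1 + CHD7)
        make_call("N2", "chr8:6:G:C"),
        make_call("N2", "chr9:7:A:T"),
        # C1: monogenic FGFR1
        make_call("C1", "chr8:1:A:G"),
        # C2: nothing
    ]
    populations = {"KS": "NFE", "nCHH": "NFE", "CDGP": "FIN", "CONTROL": "NFE"}
    return probands, variants, calls, populations
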