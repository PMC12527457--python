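"""Filter cascade: boundary behaviour, bypass semantics, monotonicity."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tierpoi.models import (
    AnnotatedCall,
    Consequence,
    FilterConfig,
    Genotype,
    VariantAnnotation,
    VariantCall,
)
from tierpoi.variant_filters import (
    acmg_retained,
    insilico_deleterious,
    passes_quality,
    passes_rarity,
    run_filter_cascade,
    synonymous_retention,
)

CFG = FilterConfig()


def call(qual=99.0, depth=75, genotype=Genotype.HET, sample="S1"):
    return VariantCall(
        chrom="chr1", pos=100, ref="C", alt="T", qual=qual, depth=depth,
        sample_id=sample, genotype=genotype,
    )


def ann(**kw):
    base = dict(
        variant_key=("chr1", 100, "C", "T"),
        gene="GENE1",
        consequence=Consequence.MISSENSE,
        gnomad_af=0.0,
        cadd=25.0,
        polyphen_damaging=True,
        sift_deleterious=True,
        acmg_class="LP",
    )
    base.update(kw)
    return VariantAnnotation(**base)


@pytest.mark.parametrize(
    "qual,depth,expected",
    [
        (20.0, 10, True),   # both thresholds are inclusive
        (19.0, 100, False),
        (75.0, 9, False),
        (20.0, 9, False),
        (1000.0, 10, True),
    ],
)
def test_quality_thresholds_inclusive(qual, depth, expected):
    assert passes_quality(call(qual=qual, depth=depth), CFG) is expected


def test_quality_missing_values_fail():
    assert not passes_quality(call(qual=None), CFG)
    assert not passes_quality(call(depth=None), CFG)


@pytest.mark.parametrize(
    "cadd,poly,sift,expected",
    [
        (16.0, False, True, True),    # two votes suffice
        (15.0, None, True, False),    # CADD 15 is not > 15; one vote
        (15.01, True, None, True),
        (None, True, True, True),
        (30.0, None, None, False),    # single vote
        (None, None, None, False),
    ],
)
def test_insilico_two_of_three(cadd, poly, sift, expected):
    a = ann(cadd=cadd, polyphen_damaging=poly, sift_deleterious=sift)
    assert insilico_deleterious(a, CFG) is expected


def test_established_variant_bypasses_insilico_and_rarity_only():
    benign = ann(
        cadd=1.0, polyphen_damaging=False, sift_deleterious=False,
        gnomad_af=0.005, established_pathogenic=True,
    )
    assert insilico_deleterious(benign, CFG)
    assert passes_rarity(benign, "monoallelic", CFG)
    # the bypass never covers quality, synonymous/splice or ACMG
    v = run_filter_cascade(
        AnnotatedCall(call=call(qual=5.0), annotation=benign), "monoallelic", CFG
    )
    assert v.bypass_used and v.failed_stages == ("quality",)
    vus = ann(established_pathogenic=True, acmg_class="VUS")
    v = run_filter_cascade(AnnotatedCall(call=call(), annotation=vus), "monoallelic", CFG)
    assert v.bypass_used and v.failed_stages == ("acmg",)


@pytest.mark.parametrize(
    "af,context,expected",
    [
        (6.195e-7, "biallelic", True),
        (0.0, "monoallelic", True),      # novel passes
        (1e-4, "biallelic", False),      # strict boundary
        (9.99e-5, "biallelic", True),
        (5e-5, "monoallelic", False),    # strict boundary
        (4.99e-5, "monoallelic", True),
        (9e-5, "monoallelic", False),    # monoallelic threshold is tighter
        (9e-5, "biallelic", True),
    ],
)
def test_rarity_strict_two_tier(af, context, expected):
    assert passes_rarity(ann(gnomad_af=af), context, CFG) is expected


def test_rarity_rejects_unknown_context():
    with pytest.raises(ValueError):
        passes_rarity(ann(), "triallelic", CFG)


@pytest.mark.parametrize(
    "consequence,offset,pred,expected",
    [
        (Consequence.MISSENSE, 0, None, True),       # rule not applicable
        (Consequence.UTR, 0, None, True),
        (Consequence.SYNONYMOUS, 0, False, False),   # synonymous excluded
        (Consequence.SYNONYMOUS, 0, True, True),     # unless splice-affecting
        (Consequence.SPLICE_SITE, 2, True, True),    # canonical site
        (Consequence.SPLICE_SITE, -1652, True, True),  # deep intronic, predicted
        (Consequence.SPLICE_SITE, 2, None, False),
        (Consequence.INTRONIC, 5, True, True),       # within the 7-base window
        (Consequence.INTRONIC, 8, True, False),      # outside the window
        (Consequence.INTRONIC, 3, False, False),
    ],
)
def test_synonymous_splice_rule(consequence, offset, pred, expected):
    a = ann(consequence=consequence, intron_offset=offset, splice_loss_predicted=pred)
    assert synonymous_retention(a, CFG) is expected


@pytest.mark.parametrize(
    "acmg,expected",
    [("P", True), ("LP", True), ("VUS", False), ("LB", False), ("B", False), (None, False)],
)
def test_acmg_retention(acmg, expected):
    assert acmg_retained(ann(acmg_class=acmg)) is expected


def test_cascade_collects_all_failed_stages():
    a = ann(gnomad_af=0.001, acmg_class="VUS", cadd=1.0,
            polyphen_damaging=False, sift_deleterious=False)
    v = run_filter_cascade(AnnotatedCall(call=call(qual=5.0), annotation=a),
                           "monoallelic", CFG)
    assert not v.passed
    assert set(v.failed_stages) == {"quality", "insilico", "rarity", "acmg"}


def test_cascade_single_stage_failure_named():
    a = ann(gnomad_af=1e-3)
    v = run_filter_cascade(AnnotatedCall(call=call(), annotation=a), "monoallelic", CFG)
    assert v.failed_stages == ("rarity",)


def test_stop_gain_hom_novel_passes():
    # a homozygous stop-gain absent from the population reference sails through
    a = ann(consequence=Consequence.STOP_GAIN, acmg_class="P", gnomad_af=0.0)
    v = run_filter_cascade(
        AnnotatedCall(call=call(genotype=Genotype.HOM_ALT), annotation=a),
        "biallelic", CFG,
    )
    assert v.passed


@given(
    qual=st.floats(0, 100),
    depth=st.integers(0, 200),
    cadd=st.floats(0, 60),
    af=st.floats(0, 1e-3),
    dq=st.floats(0, 30),
    dd=st.integers(0, 30),
    dc=st.floats(0, 20),
)
def test_tightening_thresholds_is_monotone(qual, depth, cadd, af, dq, dd, dc):
    """Tightening any threshold never turns a rejected variant into a pass."""
    a = ann(cadd=cadd, polyphen_damaging=False, sift_deleterious=True, gnomad_af=af)
    ac = AnnotatedCall(call=call(qual=qual, depth=depth), annotation=a)
    loose = FilterConfig()
    tight = FilterConfig(
        min_qual=loose.min_qual + dq,
        min_depth=loose.min_depth + dd,
        cadd_cutoff=loose.cadd_cutoff + dc,
        maf_biallelic=loose.maf_biallelic / 2,
        maf_monoallelic=loose.maf_monoallelic / 2,
    )
    for context in ("biallelic", "monoallelic"):
        if run_filter_cascade(ac, context, tight).passed:
            assert run_filter_cascade(ac, context, loose).passed


def test_every_fixture_variant_passes_cascade(table_bundle):
    """Each published table variant passes under its printed zygosity context."""
    from tierpoi.inheritance import rarity_context, resolve_gene_zygosity

    groups = {}
    for ac in table_bundle.annotated_calls():
        groups.setdefault((ac.sample_id, ac.gene), []).append(ac)
    assert groups
    for (_, _), acs in groups.items():
        z = resolve_gene_zygosity(acs)
        ctx = rarity_context(z)
        for ac in acs:
            v = run_filter_cascade(ac, ctx[ac.key], CFG)
            assert v.passed, (ac.gene, ac.annotation.hgvs_c, v.failed_stages)
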