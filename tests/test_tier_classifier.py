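"""Category routing: panel membership, expected-inheritance rerouting,
the Category-3 forward screen, and the three-pass cohort screen."""

import pytest

from tierpoi.models import GenePanelEntry, GeneZygosity
from tierpoi.tier_classifier import classify, flag_other_phenotype, run_tiered_screen

PANEL1 = {
    "STAG3": GenePanelEntry(
        gene="STAG3", category=1, tier="green",
        expected_inheritance=frozenset({"biallelic"}),
    ),
    "POLR2C": GenePanelEntry(
        gene="POLR2C", category=1, tier="amber",
        expected_inheritance=frozenset({"monoallelic"}),
    ),
}
PANEL2 = {"NLRP11": GenePanelEntry(gene="NLRP11", category=2)}


def zyg(gene, zyg_class, sample="S1"):
    return GeneZygosity(
        sample_id=sample, gene=gene,
        variants=(("chr1", 100, "A", "T"),)
        if zyg_class != "probable_compound_het"
        else (("chr1", 100, "A", "T"), ("chr1", 200, "G", "C")),
        zyg_class=zyg_class,
    )


def test_panel1_expected_inheritance_gives_category1_with_tier():
    f = classify(zyg("STAG3", "homozygous"), PANEL1, PANEL2)
    assert (f.category, f.tier, f.reroute_reason) == (1, "green", "none")
    # probable compound het counts as biallelic
    f = classify(zyg("STAG3", "probable_compound_het"), PANEL1, PANEL2)
    assert (f.category, f.tier) == (1, "green")
    f = classify(zyg("POLR2C", "heterozygous"), PANEL1, PANEL2)
    assert (f.category, f.tier) == (1, "amber")


def test_panel1_unexpected_inheritance_reroutes_to_category2():
    f = classify(zyg("STAG3", "heterozygous"), PANEL1, PANEL2)
    assert (f.category, f.reroute_reason) == (2, "unexpected_inheritance")
    f = classify(zyg("POLR2C", "homozygous"), PANEL1, PANEL2)
    assert (f.category, f.reroute_reason) == (2, "unexpected_inheritance")


def test_panel2_and_forward_screen_and_discard():
    assert classify(zyg("NLRP11", "heterozygous"), PANEL1, PANEL2).category == 2
    assert classify(zyg("NLRP11", "homozygous"), PANEL1, PANEL2).category == 2
    f = classify(zyg("ARRB1", "homozygous"), PANEL1, PANEL2)
    assert (f.category, f.tier) == (3, "none")  # unlisted gene, homozygous
    assert classify(zyg("ARRB1", "heterozygous"), PANEL1, PANEL2) is None


def test_gene_on_both_panels_is_a_configuration_error():
    bad2 = dict(PANEL2, STAG3=GenePanelEntry(gene="STAG3", category=2))
    with pytest.raises(ValueError):
        classify(zyg("STAG3", "heterozygous"), PANEL1, bad2)
    with pytest.raises(ValueError):
        run_tiered_screen([], PANEL1, bad2, [])


def test_other_phenotype_flagging():
    listed = {"PKD1L1": "situs inversus"}
    f3 = classify(zyg("PKD1L1", "homozygous"), PANEL1, PANEL2)
    flagged = flag_other_phenotype(f3, listed)
    assert flagged.other_phenotype_flag and flagged.phenotype_note == "situs inversus"
    unflagged = flag_other_phenotype(
        classify(zyg("DND1", "homozygous"), PANEL1, PANEL2), listed
    )
    assert not unflagged.other_phenotype_flag


def test_fixture_rerouting_rows(table_analysis):
    """Printed rows: a lone STAG3 het sits in Category 2; STAG3 hom in
    Category 1 Green; an individual keeps findings from several passes."""
    by = table_analysis.findings_by_sample
    (spoi52,) = by["SPOI52"]
    assert spoi52.gene == "STAG3"
    assert (spoi52.category, spoi52.reroute_reason) == (2, "unexpected_inheritance")
    (spoi15,) = by["SPOI15"]
    assert (spoi15.gene, spoi15.category, spoi15.tier) == ("STAG3", 1, "green")
    # SPOI18: Category 1 amber het plus a Category 3 homozygote, two findings
    cats = sorted((f.gene, f.category) for f in by["SPOI18"])
    assert cats == [("EIF4ENIF1", 1), ("PCIF1", 3)]
    # FPOI4 members: one Category 1 amber + five Category 2 findings
    fpoi4 = sorted((f.category) for f in by["FPOI4_A"])
    assert fpoi4 == [1, 2, 2, 2, 2, 2]
    assert table_analysis.labels_by_sample["FPOI4_A"] == "oligogenic"


def test_fixture_other_phenotype_carriers_flagged(table_analysis):
    flags = {
        (f.sample_id, f.gene)
        for fs in table_analysis.findings_by_sample.values()
        for f in fs
        if f.other_phenotype_flag
    }
    assert flags == {("SPOI28", "PKD1L1"), ("SPOI77", "ABCA4")}


def test_individual_without_passing_calls_has_no_findings(table_analysis):
    assert table_analysis.findings_by_sample.get("SPOI118", []) == []


def test_panel_ablation_property(table_bundle):
    """Without panel 2, every Category-2 het disappears and every
    Category-2 homozygote becomes Category 3."""
    base = run_tiered_screen(
        table_bundle.annotated_calls(), table_bundle.panel1,
        table_bundle.panel2, table_bundle.pedigree,
    )
    ablated = run_tiered_screen(
        table_bundle.annotated_calls(), table_bundle.panel1, {},
        table_bundle.pedigree,
    )
    base_by_key = {
        (f.sample_id, f.gene): f for fs in base.findings_by_sample.values()
        for f in fs
    }
    abl_by_key = {
        (f.sample_id, f.gene): f for fs in ablated.findings_by_sample.values()
        for f in fs
    }
    for key, f in base_by_key.items():
        if f.category != 2:
            assert key in abl_by_key and abl_by_key[key].category == f.category
        elif f.reroute_reason == "unexpected_inheritance":
            # rerouted panel-1 genes do not depend on panel 2
            assert abl_by_key[key].category == 2
        elif f.zygosity.zyg_class == "homozygous":
            assert abl_by_key[key].category == 3
        else:
            assert key not in abl_by_key
    # nothing new appears
    assert set(abl_by_key) <= set(base_by_key)
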