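"""Simulator: determinism, perfect recovery, decoy rejection, ablation,
and the on-disk bundle round-trip through the file readers."""

import json

import pytest

from tierpoi.io_formats import (
    join_annotations,
    read_annotation_table,
    read_gene_panel,
    read_other_phenotype_list,
    read_pedigree,
    read_vcf,
)
from tierpoi.pipeline import analyze, analyze_bundle
from tierpoi.synthetic_data import (
    STAGES,
    SimulationConfig,
    ablate,
    generate_cohort,
    make_table_fixtures,
    panels_by_gene,
    write_bundle,
)


def entity_map(pedigree):
    return {
        i.sample_id: (i.kindred_id if i.subcohort == "familial" else i.sample_id)
        for i in pedigree
    }


def recovered_findings(result, pedigree):
    ent = entity_map(pedigree)
    return {
        (ent[sid], f.gene, f.category)
        for sid, fs in result.findings_by_sample.items()
        for f in fs
    }


@pytest.fixture(scope="module")
def default_bundle():
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="module")
def default_analysis(default_bundle):
    return analyze_bundle(default_bundle)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(composition={"cat1_AR": 0.4})  # does not sum to 1
    with pytest.raises(ValueError):
        SimulationConfig(composition={"bogus": 1.0})
    with pytest.raises(ValueError):
        SimulationConfig(decoys_per_individual={"quality": -1})
    with pytest.raises(ValueError):
        SimulationConfig(n_familial_kindreds=3, kindred_sizes=(2, 2))


def test_same_seed_same_output(default_bundle):
    again = generate_cohort(SimulationConfig(seed=11))
    assert [c for c in again.calls] == [c for c in default_bundle.calls]
    assert again.annotations == default_bundle.annotations
    assert json.dumps(again.manifest.as_dict()) == json.dumps(
        default_bundle.manifest.as_dict()
    )
    other = generate_cohort(SimulationConfig(seed=12))
    assert other.annotations != default_bundle.annotations


def test_default_cohort_structure(default_bundle):
    ped = default_bundle.pedigree
    assert sum(1 for i in ped if i.subcohort == "sporadic") == 118
    kindreds = {i.kindred_id for i in ped if i.subcohort == "familial"}
    assert len(kindreds) == 17
    consang = {i.kindred_id for i in ped if i.consanguineous}
    assert len(consang) == 8


def test_perfect_recovery_without_decoys(default_bundle, default_analysis):
    m = default_bundle.manifest
    assert recovered_findings(default_analysis, default_bundle.pedigree) == (
        m.expected_findings()
    )
    ent = entity_map(default_bundle.pedigree)
    got_labels = {}
    for sid, lab in default_analysis.labels_by_sample.items():
        got_labels[ent[sid]] = lab
    for entity, expected in m.expected_labels().items():
        assert got_labels.get(entity) == expected, entity


def test_single_plant_recovery():
    cfg = SimulationConfig(
        seed=3, n_sporadic=1, n_familial_kindreds=0, kindred_sizes=(),
        composition={"cat1_AR": 1.0},
    )
    b = generate_cohort(cfg)
    r = analyze_bundle(b)
    findings = r.all_findings = [
        f for fs in r.findings_by_sample.values() for f in fs
    ]
    assert len(findings) == 1
    assert findings[0].category == 1
    assert findings[0].zygosity.zyg_class == "homozygous"


def test_all_no_finding_cohort_yields_nothing():
    cfg = SimulationConfig(
        seed=4, n_sporadic=20, n_familial_kindreds=0, kindred_sizes=(),
        composition={"no_finding": 1.0},
    )
    r = analyze_bundle(generate_cohort(cfg))
    assert r.findings_by_sample == {}


def test_decoys_rejected_at_constructed_stage_and_plants_survive():
    decoys = {s: 1 for s in STAGES}
    cfg = SimulationConfig(seed=5, decoys_per_individual=decoys)
    b = generate_cohort(cfg)
    r = analyze_bundle(b)
    n = len(b.pedigree)
    for stage in STAGES:
        assert r.screen.rejection_counts.get(stage, 0) == n
    assert recovered_findings(r, b.pedigree) == b.manifest.expected_findings()


@pytest.mark.parametrize("stage", STAGES)
def test_ablation_removes_every_planted_finding(stage):
    cfg = SimulationConfig(seed=6, n_sporadic=20, n_familial_kindreds=2,
                           kindred_sizes=(2, 2))
    b = generate_cohort(cfg)
    perturbed = ablate(b, stage)
    r = analyze_bundle(perturbed)
    assert r.findings_by_sample == {}
    # every planted variant is attributed to the ablated stage
    n_planted = len(b.manifest.planted_keys())
    assert r.screen.rejection_counts.get(stage, 0) >= n_planted


def test_ablate_unknown_stage_is_error(default_bundle):
    with pytest.raises(ValueError):
        ablate(default_bundle, "bogus")


def test_bundle_round_trip_through_files(tmp_path):
    """Writing a simulated bundle and re-reading it through the file
    readers reproduces the in-memory pipeline result."""
    cfg = SimulationConfig(seed=7, n_sporadic=12, n_familial_kindreds=3,
                           kindred_sizes=(2, 2, 1))
    b = generate_cohort(cfg)
    r_mem = analyze_bundle(b)

    paths = write_bundle(b, tmp_path)
    ped = read_pedigree(paths["pedigree"])
    calls = list(read_vcf(paths["vcf"], known_samples=[i.sample_id for i in ped]))
    anns = read_annotation_table(paths["annotations"])
    annotated, sink = join_annotations(calls, anns)
    assert sink == []
    r_file = analyze(
        annotated,
        panels_by_gene(read_gene_panel(paths["panel1"])),
        panels_by_gene(read_gene_panel(paths["panel2"])),
        ped,
        other_phenotype=read_other_phenotype_list(paths["other_phenotype"]),
    )
    assert recovered_findings(r_file, ped) == recovered_findings(r_mem, b.pedigree)
    assert r_file.summary.as_dict() == r_mem.summary.as_dict()


def test_write_bundle_is_hash_stable(tmp_path):
    import hashlib

    cfg = SimulationConfig(seed=9, n_sporadic=5, n_familial_kindreds=1,
                           kindred_sizes=(2,))
    digests = []
    for sub in ("a", "b"):
        paths = write_bundle(generate_cohort(cfg), tmp_path / sub)
        digest = hashlib.sha256()
        for name in sorted(paths):
            digest.update(paths[name].read_bytes())
        digests.append(digest.hexdigest())
    assert digests[0] == digests[1]


def test_table_fixture_shape():
    b = make_table_fixtures()
    sporadic = [i for i in b.pedigree if i.subcohort == "sporadic"]
    familial = [i for i in b.pedigree if i.subcohort == "familial"]
    assert len(sporadic) == 118
    assert len({i.kindred_id for i in familial}) == 17
    assert len(familial) == 31
    with_rows = {c.sample_id for c in b.calls if c.sample_id.startswith("SPOI")}
    assert len(with_rows) == 77  # SPOI78-118 are finding-free
    # the Category 3 gene set of the candidate table
    cat3_genes = {
        a.gene for a in b.annotations
        if a.gene not in b.panel1 and a.gene not in b.panel2
    }
    assert cat3_genes == {
        "PCIF1", "MMS22L", "PKD1L1", "DND1", "MEF2A", "RXFP3", "ARRB1",
        "C4ORF33", "ABCA4",
    }
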