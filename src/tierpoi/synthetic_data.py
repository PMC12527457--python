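"""Synthetic cohorts and literal table fixtures.

Two sources of test data live here:

* :func:`make_table_fixtures` expands the published variant tables of the
  familial and sporadic cohorts (shipped as TSV files under ``data/``)
  into annotated calls, a pedigree and the two gene panels, so that every
  printed detection-rate statistic can be recomputed offline.
* :func:`generate_cohort` simulates a fully synthetic cohort from a seed
  and a composition config, with planted findings recorded in a truth
  manifest and optional decoy variants that each violate exactly one
  cascade stage.

The synthetic genome is an invented contig set with invented gene
coordinates; the pipeline never needs real coordinates. Fixture population
frequencies are the literal printed values.
"""

from __future__ import annotations

import csv
import json
import re
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io_formats import join_annotations, read_gene_panel, read_other_phenotype_list
from .models import (
    AnnotatedCall,
    Consequence,
    FilterConfig,
    GenePanelEntry,
    Genotype,
    Individual,
    VariantAnnotation,
    VariantCall,
)

__all__ = [
    "CohortBundle",
    "SimulationConfig",
    "TruthManifest",
    "make_table_fixtures",
    "generate_cohort",
    "ablate",
    "write_bundle",
    "panels_by_gene",
]

_DATA = Path(__file__).parent / "data"

# genes on the X chromosome in the fixture tables (cohort is 46,XX; X hets
# behave exactly like autosomal hets)
_X_GENES = {"BMP15", "FOXO4", "IRS4"}

POPULATION_AN = 1_600_000


def panels_by_gene(entries: Sequence[GenePanelEntry]) -> Dict[str, GenePanelEntry]:
    return {e.gene: e for e in entries}


@dataclass
class CohortBundle:
    """Everything one pipeline run needs, in memory."""

    calls: List[VariantCall]
    annotations: List[VariantAnnotation]
    pedigree: List[Individual]
    panel1: Dict[str, GenePanelEntry]
    panel2: Dict[str, GenePanelEntry]
    other_phenotype: Dict[str, str]
    manifest: Optional["TruthManifest"] = None

    def annotated_calls(self) -> List[AnnotatedCall]:
        annotated, sink = join_annotations(self.calls, self.annotations)
        if sink:
            raise AssertionError(f"{len(sink)} bundle calls lack annotations")
        return annotated


# ---------------------------------------------------------------------------
# table fixtures


_SPLICE_RE = re.compile(r"\d+([+-]\d+)")
_SNV_RE = re.compile(r"([ACGT])>([ACGT])")


def _infer_consequence(hgvs_c: str, hgvs_p: str) -> Tuple[str, int]:
    """Coarse consequence and intron offset from the HGVS strings.

    Intronic positions become splice_site (every retained intronic variant
    in the tables is either at a canonical site or carried a positive
    splice prediction); frameshift and stop-gain come from the protein
    change; ``c.-`` positions without an intron offset are UTR.
    """
    m = _SPLICE_RE.search(hgvs_c)
    if m:
        return Consequence.SPLICE_SITE, int(m.group(1))
    if "fs" in hgvs_p:
        return Consequence.FRAMESHIFT, 0
    if hgvs_p.endswith("*"):
        return Consequence.STOP_GAIN, 0
    if hgvs_c.startswith("c.-"):
        return Consequence.UTR, 0
    return Consequence.MISSENSE, 0


class _VariantRegistry:
    """Deterministic invented coordinates for (gene, hgvs_c) pairs."""

    def __init__(self):
        self._keys: Dict[Tuple[str, str], tuple] = {}
        self._counter: Dict[str, int] = {}

    def key_for(self, gene: str, hgvs_c: str) -> tuple:
        k = (gene, hgvs_c)
        if k in self._keys:
            return self._keys[k]
        if gene in _X_GENES:
            chrom = "chrX"
        else:
            chrom = f"chr{1 + zlib.crc32(gene.encode()) % 22}"
        self._counter[gene] = self._counter.get(gene, 0) + 1
        base = 100_000 * (1 + zlib.crc32((gene + "#pos").encode()) % 2000)
        pos = base + 10 * self._counter[gene]
        m = _SNV_RE.search(hgvs_c)
        if m:
            ref, alt = m.group(1), m.group(2)
        elif "del" in hgvs_c:
            ref, alt = "CA", "C"
        elif "dup" in hgvs_c or "ins" in hgvs_c:
            ref, alt = "C", "CA"
        else:
            ref, alt = "A", "T"
        key = (chrom, pos, ref, alt)
        self._keys[k] = key
        return key


def _read_fixture_rows(name: str) -> List[dict]:
    with open(_DATA / name) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


_FAMILIAL_CONSANGUINEOUS = {
    "FPOI1",
    "FPOI2",
    "FPOI3",
    "FPOI5",
    "FPOI6",
    "FPOI8",
    "FPOI11",
    "FPOI12",
}
# recruited affected members per kindred: 20 across the 11 kindreds with
# findings, 11 across the 6 without, 31 in total
_FAMILIAL_SIZES = {
    **{f"FPOI{i}": 2 for i in range(1, 10)},
    "FPOI10": 1,
    "FPOI11": 1,
    **{f"FPOI{i}": 2 for i in range(12, 17)},
    "FPOI17": 1,
}
_SPORADIC_CONSANGUINEOUS = {"SPOI4", "SPOI17", "SPOI25", "SPOI77"}


def _fixture_pedigree() -> List[Individual]:
    pedigree: List[Individual] = []
    for i in range(1, 119):
        sid = f"SPOI{i}"
        pedigree.append(
            Individual(
                sample_id=sid,
                kindred_id=sid,
                affected=True,
                subcohort="sporadic",
                consanguineous=sid in _SPORADIC_CONSANGUINEOUS,
            )
        )
    for k in range(1, 18):
        kid = f"FPOI{k}"
        size = _FAMILIAL_SIZES[kid]
        for m in range(size):
            pedigree.append(
                Individual(
                    sample_id=f"{kid}_{chr(ord('A') + m)}",
                    kindred_id=kid,
                    affected=True,
                    subcohort="familial",
                    consanguineous=kid in _FAMILIAL_CONSANGUINEOUS,
                    external_affected=(size == 1),
                )
            )
    return pedigree


def make_table_fixtures(cfg: Optional[FilterConfig] = None) -> CohortBundle:
    """Expand the published familial and sporadic variant tables.

    Every printed row becomes an annotated call per recruited affected
    carrier. Annotations are constructed to satisfy the cascade the way
    the published screen retained them: high call quality, damaging
    in-silico verdicts, P/LP class, positive splice predictions for
    intronic variants, and the established-POI bypass flag for the
    variants whose printed population frequency exceeds the mechanical
    threshold of their zygosity context.
    """
    cfg = cfg or FilterConfig()
    registry = _VariantRegistry()
    pedigree = _fixture_pedigree()

    fam_rows = _read_fixture_rows("table_familial.tsv")
    spo_rows = _read_fixture_rows("table_sporadic.tsv")

    # carriers per row: the sporadic individual, or every affected kindred
    # member for familial rows
    expanded: List[dict] = []
    for row in fam_rows:
        kid = row["kindred"]
        for m in range(_FAMILIAL_SIZES[kid]):
            expanded.append({**row, "sample": f"{kid}_{chr(ord('A') + m)}"})
    expanded.extend(spo_rows)

    # context per (sample, gene): biallelic when any member row is
    # homozygous or the sample carries >=2 variants in the gene
    rows_by_group: Dict[Tuple[str, str], List[dict]] = {}
    for row in expanded:
        rows_by_group.setdefault((row["sample"], row["gene"]), []).append(row)
    needs_bypass: Dict[Tuple[str, str], bool] = {}
    for (_, gene), rows in rows_by_group.items():
        biallelic = any(r["zygosity"] == "biallelic" for r in rows) or len(rows) >= 2
        threshold = cfg.maf_biallelic if biallelic else cfg.maf_monoallelic
        for r in rows:
            vk = (gene, r["hgvs_c"])
            if float(r["gnomad_af"]) >= threshold:
                needs_bypass[vk] = True

    calls: List[VariantCall] = []
    annotations: Dict[tuple, VariantAnnotation] = {}
    for row in expanded:
        gene, hgvs_c, hgvs_p = row["gene"], row["hgvs_c"], row["hgvs_p"]
        hgvs_p = "" if hgvs_p == "." else hgvs_p
        key = registry.key_for(gene, hgvs_c)
        af = float(row["gnomad_af"])
        consequence, offset = _infer_consequence(hgvs_c, hgvs_p)
        if key not in annotations:
            annotations[key] = VariantAnnotation(
                variant_key=key,
                gene=gene,
                transcript=row["transcript"],
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                consequence=consequence,
                intron_offset=offset,
                gnomad_af=af,
                gnomad_ac=round(af * POPULATION_AN),
                gnomad_an=POPULATION_AN,
                cadd=25.0,
                polyphen_damaging=True,
                sift_deleterious=True,
                acmg_class="P"
                if consequence in (Consequence.STOP_GAIN, Consequence.FRAMESHIFT)
                else "LP",
                splice_loss_predicted=True
                if consequence == Consequence.SPLICE_SITE
                else None,
                established_pathogenic=needs_bypass.get((gene, hgvs_c), False),
            )
        calls.append(
            VariantCall(
                chrom=key[0],
                pos=key[1],
                ref=key[2],
                alt=key[3],
                qual=99.0,
                depth=75,
                sample_id=row["sample"],
                genotype=Genotype.HOM_ALT
                if row["zygosity"] == "biallelic"
                else Genotype.HET,
            )
        )

    return CohortBundle(
        calls=calls,
        annotations=list(annotations.values()),
        pedigree=pedigree,
        panel1=panels_by_gene(read_gene_panel(_DATA / "panel1.tsv")),
        panel2=panels_by_gene(read_gene_panel(_DATA / "panel2.tsv")),
        other_phenotype=read_other_phenotype_list(_DATA / "other_phenotype.tsv"),
    )


# ---------------------------------------------------------------------------
# simulator


PLANT_CLASSES = (
    "cat1_AR",
    "cat1_AD",
    "cat1_CH",
    "cat2_AD",
    "cat2_CH",
    "oligogenic",
    "cat3_hom",
    "other_phenotype_hom",
    "no_finding",
)

# composition defaults mirror the published sporadic-cohort proportions
_DEFAULT_COMPOSITION = {
    "cat1_AR": 8 / 118,
    "cat1_AD": 14 / 118,
    "cat1_CH": 3 / 118,
    "cat2_AD": 34 / 118,
    "cat2_CH": 1 / 118,
    "oligogenic": 26 / 118,
    "cat3_hom": 2 / 118,
    "other_phenotype_hom": 1 / 118,
    "no_finding": 29 / 118,
}

_EXPECTED_LABEL = {
    "cat1_AR": "AR",
    "cat1_AD": "AD",
    "cat1_CH": "CH",
    "cat2_AD": "AD",
    "cat2_CH": "CH",
    "oligogenic": "oligogenic",
    "cat3_hom": None,
    "other_phenotype_hom": None,
    "no_finding": None,
}

STAGES = ("quality", "insilico", "rarity", "synonymous_splice", "acmg")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort structure and planted composition of a simulated run."""

    n_sporadic: int = 118
    n_familial_kindreds: int = 17
    kindred_sizes: tuple = tuple([2] * 14 + [1] * 3)
    consanguineous_fraction: float = 8 / 17
    composition: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COMPOSITION)
    )
    decoys_per_individual: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.composition) - set(PLANT_CLASSES)
        if unknown:
            raise ValueError(f"unknown plant classes: {sorted(unknown)}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition must sum to 1, got {total}")
        if any(v < 0 for v in self.decoys_per_individual.values()):
            raise ValueError("decoy counts must be >= 0")
        if set(self.decoys_per_individual) - set(STAGES):
            raise ValueError("decoy keys must name cascade stages")
        if len(self.kindred_sizes) != self.n_familial_kindreds:
            raise ValueError("kindred_sizes length must match n_familial_kindreds")


@dataclass
class ManifestEntry:
    entity_id: str  # sample id (sporadic) or kindred id (familial)
    entity_type: str  # individual | kindred
    plant_class: str
    genes: tuple = ()
    variant_keys: tuple = ()
    zygosities: tuple = ()  # per gene
    categories: tuple = ()  # per gene
    expected_label: Optional[str] = None


@dataclass
class TruthManifest:
    entries: List[ManifestEntry]
    decoy_keys_by_stage: Dict[str, List[tuple]] = field(default_factory=dict)

    def expected_findings(self) -> set:
        out = set()
        for e in self.entries:
            for gene, cat in zip(e.genes, e.categories):
                out.add((e.entity_id, gene, cat))
        return out

    def expected_labels(self) -> Dict[str, Optional[str]]:
        return {
            e.entity_id: e.expected_label
            for e in self.entries
            if e.plant_class != "no_finding"
        }

    def planted_keys(self) -> set:
        return {k for e in self.entries for k in e.variant_keys}

    def as_dict(self) -> dict:
        return {
            "entries": [
                {
                    "entity_id": e.entity_id,
                    "entity_type": e.entity_type,
                    "plant_class": e.plant_class,
                    "genes": list(e.genes),
                    "variant_keys": [list(k) for k in e.variant_keys],
                    "zygosities": list(e.zygosities),
                    "categories": list(e.categories),
                    "expected_label": e.expected_label,
                }
                for e in self.entries
            ],
            "decoys": {
                s: [list(k) for k in ks]
                for s, ks in self.decoy_keys_by_stage.items()
            },
        }


def _sim_panels() -> Tuple[Dict[str, GenePanelEntry], Dict[str, GenePanelEntry]]:
    panel1 = {}
    for i in range(1, 9):
        g = f"SIM1BA{i:02d}"  # biallelic-expected, green
        panel1[g] = GenePanelEntry(
            gene=g,
            category=1,
            tier="green",
            expected_inheritance=frozenset({"biallelic"}),
        )
    for i in range(1, 9):
        g = f"SIM1MA{i:02d}"  # monoallelic-expected, amber
        panel1[g] = GenePanelEntry(
            gene=g,
            category=1,
            tier="amber",
            expected_inheritance=frozenset({"monoallelic"}),
        )
    panel2 = {}
    for i in range(1, 41):
        g = f"SIM2G{i:02d}"
        panel2[g] = GenePanelEntry(gene=g, category=2)
    return panel1, panel2


_NOVEL_GENES = [f"SIM3G{i:02d}" for i in range(1, 21)]
_OPHEN_GENES = {"SIMOP01": "unrelated phenotype A", "SIMOP02": "unrelated phenotype B"}


class _SimVariantFactory:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self._pos = 0

    def new(
        self,
        gene: str,
        context: str,
        *,
        consequence: str = Consequence.MISSENSE,
        cadd: float | None = None,
        polyphen: Optional[bool] = True,
        sift: Optional[bool] = True,
        acmg: Optional[str] = "LP",
        af: Optional[float] = None,
        qual: Optional[float] = None,
        depth: Optional[int] = None,
    ) -> Tuple[tuple, VariantAnnotation, float, int]:
        self._pos += 10
        ref, alt = self.rng.choice(["A", "C", "G", "T"], size=2, replace=False)
        key = ("sim1", self._pos, str(ref), str(alt))
        if af is None:
            cap = 0.9 * (1e-4 if context == "biallelic" else 5e-5)
            af = 0.0 if self.rng.random() < 0.5 else float(self.rng.uniform(0, cap))
        if cadd is None:
            cadd = float(self.rng.uniform(16, 40))
        ann = VariantAnnotation(
            variant_key=key,
            gene=gene,
            transcript=f"SIM_{gene}",
            hgvs_c=f"c.{self._pos}{ref}>{alt}",
            consequence=consequence,
            gnomad_af=af,
            gnomad_ac=round(af * POPULATION_AN),
            gnomad_an=POPULATION_AN,
            cadd=cadd,
            polyphen_damaging=polyphen,
            sift_deleterious=sift,
            acmg_class=acmg,
            splice_loss_predicted=None,
        )
        qual = float(self.rng.uniform(30, 100)) if qual is None else qual
        depth = int(self.rng.integers(20, 150)) if depth is None else depth
        return key, ann, qual, depth


def _plant(
    factory,
    entity_genes: List[Tuple[str, str, str]],
    carriers: Sequence[str],
    calls,
    annotations,
):
    """entity_genes: (gene, zygosity_class, context) per gene; returns keys
    and per-gene zygosity strings."""
    keys = []
    zygs = []
    for gene, zyg, context in entity_genes:
        n_vars = 2 if zyg == "probable_compound_het" else 1
        gt = Genotype.HOM_ALT if zyg == "homozygous" else Genotype.HET
        for _ in range(n_vars):
            key, ann, qual, depth = factory.new(gene, context)
            annotations[key] = ann
            for sid in carriers:
                calls.append(
                    VariantCall(
                        chrom=key[0],
                        pos=key[1],
                        ref=key[2],
                        alt=key[3],
                        qual=qual,
                        depth=depth,
                        sample_id=sid,
                        genotype=gt,
                    )
                )
            keys.append(key)
        zygs.append(zyg)
    return tuple(keys), tuple(zygs)


_CLASS_GENES = {
    # plant class -> list of (gene pool, zygosity, category)
    "cat1_AR": [("p1_bi", "homozygous", 1)],
    "cat1_AD": [("p1_mono", "heterozygous", 1)],
    "cat1_CH": [("p1_bi", "probable_compound_het", 1)],
    "cat2_AD": [("p2", "heterozygous", 2)],
    "cat2_CH": [("p2", "probable_compound_het", 2)],
    "oligogenic": [("p1_mono", "heterozygous", 1), ("p2", "heterozygous", 2)],
    "cat3_hom": [("novel", "homozygous", 3)],
    "other_phenotype_hom": [("ophen", "homozygous", 3)],
    "no_finding": [],
}


def generate_cohort(cfg: SimulationConfig) -> CohortBundle:
    """Simulate a cohort; same seed and config give identical output."""
    rng = np.random.default_rng(cfg.seed)
    factory = _SimVariantFactory(rng)
    panel1, panel2 = _sim_panels()

    pools = {
        "p1_bi": sorted(g for g in panel1 if "BA" in g),
        "p1_mono": sorted(g for g in panel1 if "MA" in g),
        "p2": sorted(panel2),
        "novel": list(_NOVEL_GENES),
        "ophen": sorted(_OPHEN_GENES),
    }
    classes = [c for c in PLANT_CLASSES if c in cfg.composition]
    probs = np.array([cfg.composition[c] for c in classes])
    probs = probs / probs.sum()

    pedigree: List[Individual] = []
    calls: List[VariantCall] = []
    annotations: Dict[tuple, VariantAnnotation] = {}
    entries: List[ManifestEntry] = []

    # sporadic individuals
    sporadic_ids = [f"SIM_S{i:03d}" for i in range(1, cfg.n_sporadic + 1)]
    sporadic_classes = rng.choice(classes, size=cfg.n_sporadic, p=probs)
    for sid, pc in zip(sporadic_ids, sporadic_classes):
        pedigree.append(
            Individual(
                sample_id=sid, kindred_id=sid, affected=True, subcohort="sporadic"
            )
        )
        entries.append(
            _plant_entity(str(pc), sid, "individual", [sid], pools, rng, factory,
                          calls, annotations)
        )

    # familial kindreds; consanguineous kindreds preferentially receive the
    # homozygous plant classes
    n_consang = round(cfg.consanguineous_fraction * cfg.n_familial_kindreds)
    kindred_ids = [f"SIM_K{i:02d}" for i in range(1, cfg.n_familial_kindreds + 1)]
    fam_classes = [str(c) for c in rng.choice(classes, size=len(kindred_ids), p=probs)]
    hom_first = sorted(
        fam_classes,
        key=lambda c: 0 if c in ("cat1_AR", "cat3_hom", "other_phenotype_hom") else 1,
    )
    for idx, (kid, pc) in enumerate(zip(kindred_ids, hom_first)):
        size = cfg.kindred_sizes[idx]
        members = [f"{kid}_{chr(ord('A') + m)}" for m in range(size)]
        for sid in members:
            pedigree.append(
                Individual(
                    sample_id=sid,
                    kindred_id=kid,
                    affected=True,
                    subcohort="familial",
                    consanguineous=idx < n_consang,
                    external_affected=(size == 1),
                )
            )
        entries.append(
            _plant_entity(pc, kid, "kindred", members, pools, rng, factory,
                          calls, annotations)
        )

    # decoys, each violating exactly one named stage
    decoy_keys: Dict[str, List[tuple]] = {s: [] for s in STAGES}
    used_genes = {e.entity_id: set(e.genes) for e in entries}
    entity_of = {
        i.sample_id: (i.kindred_id if i.subcohort == "familial" else i.sample_id)
        for i in pedigree
    }
    for sid in (i.sample_id for i in pedigree):
        banned = used_genes.get(entity_of[sid], set())
        free = [g for g in pools["p2"] if g not in banned]
        gi = 0
        for stage in STAGES:
            for _ in range(cfg.decoys_per_individual.get(stage, 0)):
                gene = free[gi % len(free)]
                gi += 1
                key, ann, qual, depth = _decoy_variant(factory, gene, stage)
                annotations[key] = ann
                calls.append(
                    VariantCall(
                        chrom=key[0],
                        pos=key[1],
                        ref=key[2],
                        alt=key[3],
                        qual=qual,
                        depth=depth,
                        sample_id=sid,
                        genotype=Genotype.HET,
                    )
                )
                decoy_keys[stage].append(key)

    manifest = TruthManifest(
        entries=entries,
        decoy_keys_by_stage={s: ks for s, ks in decoy_keys.items() if ks},
    )
    return CohortBundle(
        calls=calls,
        annotations=list(annotations.values()),
        pedigree=pedigree,
        panel1=panel1,
        panel2=panel2,
        other_phenotype=dict(_OPHEN_GENES),
        manifest=manifest,
    )


def _plant_entity(
    plant_class, entity_id, entity_type, carriers, pools, rng, factory, calls,
    annotations,
) -> ManifestEntry:
    spec = _CLASS_GENES[plant_class]
    entity_genes = []
    cats = []
    for pool_name, zyg, cat in spec:
        pool = pools[pool_name]
        gene = str(pool[int(rng.integers(len(pool)))])
        while any(g == gene for g, _, _ in entity_genes):
            gene = str(pool[int(rng.integers(len(pool)))])
        context = (
            "biallelic" if zyg in ("homozygous", "probable_compound_het")
            else "monoallelic"
        )
        entity_genes.append((gene, zyg, context))
        cats.append(cat)
    keys, zygs = _plant(factory, entity_genes, carriers, calls, annotations)
    return ManifestEntry(
        entity_id=entity_id,
        entity_type=entity_type,
        plant_class=plant_class,
        genes=tuple(g for g, _, _ in entity_genes),
        variant_keys=keys,
        zygosities=zygs,
        categories=tuple(cats),
        expected_label=_EXPECTED_LABEL[plant_class],
    )


def _decoy_variant(factory, gene, stage):
    if stage == "quality":
        return factory.new(gene, "monoallelic", qual=5.0, af=0.0)
    if stage == "insilico":
        return factory.new(
            gene, "monoallelic", cadd=2.0, polyphen=False, sift=False, af=0.0
        )
    if stage == "rarity":
        return factory.new(gene, "monoallelic", af=0.01)
    if stage == "synonymous_splice":
        return factory.new(
            gene, "monoallelic", consequence=Consequence.SYNONYMOUS, af=0.0
        )
    if stage == "acmg":
        return factory.new(gene, "monoallelic", acmg="VUS", af=0.0)
    raise ValueError(f"unknown stage {stage!r}")


def ablate(bundle: CohortBundle, stage: str) -> CohortBundle:
    """Perturb every planted variant to violate exactly ``stage``."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    if bundle.manifest is None:
        raise ValueError("ablate requires a bundle with a truth manifest")
    planted = bundle.manifest.planted_keys()
    calls = bundle.calls
    annotations = bundle.annotations
    if stage == "quality":
        calls = [
            replace(c, qual=5.0) if c.key in planted else c for c in calls
        ]
    else:
        new_anns = []
        for ann in annotations:
            if ann.variant_key not in planted:
                new_anns.append(ann)
                continue
            if stage == "insilico":
                ann = replace(
                    ann,
                    cadd=2.0,
                    polyphen_damaging=False,
                    sift_deleterious=False,
                    established_pathogenic=False,
                )
            elif stage == "rarity":
                ann = replace(
                    ann,
                    gnomad_af=0.02,
                    gnomad_ac=round(0.02 * POPULATION_AN),
                    established_pathogenic=False,
                )
            elif stage == "synonymous_splice":
                ann = replace(
                    ann,
                    consequence=Consequence.SYNONYMOUS,
                    intron_offset=0,
                    splice_loss_predicted=None,
                )
            elif stage == "acmg":
                ann = replace(ann, acmg_class="VUS")
            new_anns.append(ann)
        annotations = new_anns
    return CohortBundle(
        calls=calls,
        annotations=annotations,
        pedigree=bundle.pedigree,
        panel1=bundle.panel1,
        panel2=bundle.panel2,
        other_phenotype=bundle.other_phenotype,
        manifest=bundle.manifest,
    )


# ---------------------------------------------------------------------------
# on-disk emission (the exact formats io_formats reads)


def write_bundle(bundle: CohortBundle, out_dir) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    samples = [i.sample_id for i in bundle.pedigree]
    by_key: Dict[tuple, Dict[str, VariantCall]] = {}
    for c in bundle.calls:
        by_key.setdefault(c.key, {})[c.sample_id] = c

    def _chrom_sort(k):
        return (k[0], k[1], k[2], k[3])

    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for contig in sorted({k[0] for k in by_key}):
        lines.append(f"##contig=<ID={contig}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    gt_code = {Genotype.HET: "0/1", Genotype.HOM_ALT: "1/1", Genotype.HOM_REF: "0/0"}
    for key in sorted(by_key, key=_chrom_sort):
        carriers = by_key[key]
        qual = min(c.qual for c in carriers.values())
        cols = [key[0], str(key[1]), ".", key[2], key[3], f"{qual:g}", "PASS", ".", "GT:DP"]
        for s in samples:
            c = carriers.get(s)
            if c is None:
                cols.append("0/0:50")
            else:
                cols.append(f"{gt_code.get(c.genotype, './.')}:{c.depth}")
        lines.append("\t".join(cols))
    p = out_dir / "cohort.vcf"
    p.write_text("\n".join(lines) + "\n")
    paths["vcf"] = p

    header = [
        "chrom", "pos", "ref", "alt", "gene", "transcript", "hgvs_c", "hgvs_p",
        "consequence", "intron_offset", "gnomad_af", "gnomad_ac", "gnomad_an",
        "cadd", "polyphen_damaging", "sift_deleterious", "acmg_class",
        "splice_loss_predicted", "established_pathogenic",
    ]
    rows = ["\t".join(header)]
    def _b(v):
        return "" if v is None else str(int(v))
    for ann in sorted(bundle.annotations, key=lambda a: _chrom_sort(a.variant_key)):
        rows.append(
            "\t".join(
                [
                    ann.variant_key[0], str(ann.variant_key[1]),
                    ann.variant_key[2], ann.variant_key[3], ann.gene,
                    ann.transcript, ann.hgvs_c, ann.hgvs_p, ann.consequence,
                    str(ann.intron_offset), repr(ann.gnomad_af),
                    "" if ann.gnomad_ac is None else str(ann.gnomad_ac),
                    "" if ann.gnomad_an is None else str(ann.gnomad_an),
                    "" if ann.cadd is None else repr(ann.cadd),
                    _b(ann.polyphen_damaging), _b(ann.sift_deleterious),
                    ann.acmg_class or "", _b(ann.splice_loss_predicted),
                    str(int(ann.established_pathogenic)),
                ]
            )
        )
    p = out_dir / "annotations.tsv"
    p.write_text("\n".join(rows) + "\n")
    paths["annotations"] = p

    rows = []
    for i in bundle.pedigree:
        rows.append(
            " ".join(
                [
                    i.kindred_id, i.sample_id, i.father_id or "0",
                    i.mother_id or "0", "2", "2" if i.affected else "1",
                    i.subcohort, str(int(i.consanguineous)),
                    str(int(i.external_affected)),
                ]
            )
        )
    p = out_dir / "pedigree.ped"
    p.write_text("\n".join(rows) + "\n")
    paths["pedigree"] = p

    for name, panel in (("panel1", bundle.panel1), ("panel2", bundle.panel2)):
        rows = ["gene\tcategory\ttier\texpected_inheritance\tsource_note"]
        for g in sorted(panel):
            e = panel[g]
            rows.append(
                "\t".join(
                    [
                        e.gene, str(e.category),
                        e.tier if e.category == 1 else "none",
                        ",".join(sorted(e.expected_inheritance)), e.source_note,
                    ]
                )
            )
        p = out_dir / f"{name}.tsv"
        p.write_text("\n".join(rows) + "\n")
        paths[name] = p

    rows = ["gene\tphenotype"]
    for g in sorted(bundle.other_phenotype):
        rows.append(f"{g}\t{bundle.other_phenotype[g]}")
    p = out_dir / "other_phenotype.tsv"
    p.write_text("\n".join(rows) + "\n")
    paths["other_phenotype"] = p

    if bundle.manifest is not None:
        p = out_dir / "manifest.json"
        p.write_text(json.dumps(bundle.manifest.as_dict(), indent=2) + "\n")
        paths["manifest"] = p
    return paths
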