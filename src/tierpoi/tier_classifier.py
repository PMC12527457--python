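"""Three-tier category routing of filter-passed findings.

Decision order for one resolved gene zygosity:

1. gene on panel 1 and zygosity compatible with its expected inheritance
   -> Category 1, with the panel tier;
2. gene on panel 1 but zygosity incompatible (e.g. a lone heterozygote in
   a recessive gene) -> Category 2, reroute_reason=unexpected_inheritance;
3. gene on panel 2 -> Category 2;
4. homozygous in a gene on neither panel -> Category 3 (forward screen for
   novel candidates);
5. otherwise discard (heterozygous in an unlisted gene).

A probable compound heterozygote counts as biallelic for the
expected-inheritance match.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .enrichment_stats import variant_enrichment
from .inheritance import rarity_context, resolve_gene_zygosity
from .models import (
    AnnotatedCall,
    CategorizedFinding,
    FilterConfig,
    GenePanelEntry,
    GeneZygosity,
    Genotype,
    Individual,
)
from .variant_filters import run_filter_cascade

__all__ = [
    "classify",
    "run_tiered_screen",
    "flag_other_phenotype",
    "ScreenResult",
]


def _zygosity_model(zyg_class: str) -> str:
    return (
        "biallelic"
        if zyg_class in ("homozygous", "probable_compound_het")
        else "monoallelic"
    )


def classify(
    z: GeneZygosity,
    panel1: Mapping[str, GenePanelEntry],
    panel2: Mapping[str, GenePanelEntry],
) -> Optional[CategorizedFinding]:
    """Assign a category to one gene zygosity, or None to discard."""
    if z.gene in panel1 and z.gene in panel2:
        raise ValueError(f"gene {z.gene} present on both panels")
    model = _zygosity_model(z.zyg_class)
    if z.gene in panel1:
        entry = panel1[z.gene]
        if model in entry.expected_inheritance:
            return CategorizedFinding(zygosity=z, category=1, tier=entry.tier)
        return CategorizedFinding(
            zygosity=z, category=2, reroute_reason="unexpected_inheritance"
        )
    if z.gene in panel2:
        return CategorizedFinding(zygosity=z, category=2)
    if z.zyg_class == "homozygous":
        return CategorizedFinding(zygosity=z, category=3)
    return None


def flag_other_phenotype(
    finding: CategorizedFinding, other_phenotype_genes: Mapping[str, str]
) -> CategorizedFinding:
    """Flag a finding whose gene explains a non-ovarian phenotype.

    Flagged findings are kept in reports but excluded from candidate
    counts.
    """
    if finding.gene in other_phenotype_genes:
        return CategorizedFinding(
            zygosity=finding.zygosity,
            category=finding.category,
            tier=finding.tier,
            reroute_reason=finding.reroute_reason,
            other_phenotype_flag=True,
            phenotype_note=other_phenotype_genes[finding.gene],
        )
    return finding


class ScreenResult:
    """Findings per individual plus the per-stage rejection log."""

    def __init__(
        self,
        findings_by_sample: Dict[str, List[CategorizedFinding]],
        rejection_counts: Dict[str, int],
        pass_counts: Dict[str, int],
        enrichment=None,
    ):
        self.findings_by_sample = findings_by_sample
        self.rejection_counts = dict(rejection_counts)
        self.pass_counts = dict(pass_counts)
        self.enrichment = enrichment or []

    def findings_for(self, sample_id: str) -> List[CategorizedFinding]:
        return self.findings_by_sample.get(sample_id, [])

    def all_findings(self) -> List[CategorizedFinding]:
        return [f for fs in self.findings_by_sample.values() for f in fs]


def _survivors_fixed_point(
    calls: Sequence[AnnotatedCall], cfg: FilterConfig, rejection: Dict[str, int]
) -> List[AnnotatedCall]:
    """Apply the cascade with zygosity-dependent rarity context to a fixed
    point for one (sample, gene) group.

    Dropping a member of a compound-het pair demotes the survivor to the
    monoallelic context, which is then re-checked; the surviving set only
    shrinks, so the loop terminates.
    """
    current = list(calls)
    while current:
        z = resolve_gene_zygosity(current)
        ctx = rarity_context(z)
        kept, dropped_stages = [], []
        for ac in current:
            verdict = run_filter_cascade(ac, ctx[ac.key], cfg)
            if verdict.passed:
                kept.append(ac)
            else:
                dropped_stages.append(verdict.failed_stages)
        if len(kept) == len(current):
            return kept
        for stages in dropped_stages:
            for s in stages:
                rejection[s] = rejection.get(s, 0) + 1
        current = kept
    return []


def run_tiered_screen(
    annotated_calls: Iterable[AnnotatedCall],
    panel1: Mapping[str, GenePanelEntry],
    panel2: Mapping[str, GenePanelEntry],
    pedigree: Sequence[Individual],
    cfg: Optional[FilterConfig] = None,
    other_phenotype_genes: Optional[Mapping[str, str]] = None,
) -> ScreenResult:
    """Run the cascade and the three category passes over a cohort.

    Pass 1 screens the whole cohort for Category 1 findings, pass 2 for
    Category 2 (including individuals already holding a Category 1
    finding), pass 3 cohort-wide for Category 3 homozygotes. Only calls of
    affected individuals are screened; genotypes without the alt allele
    are ignored.
    """
    cfg = cfg or FilterConfig()
    other_phenotype_genes = other_phenotype_genes or {}
    overlap = set(panel1) & set(panel2)
    if overlap:
        raise ValueError(f"genes on both panels: {sorted(overlap)}")

    affected = {i.sample_id for i in pedigree if i.affected}
    groups: Dict[Tuple[str, str], List[AnnotatedCall]] = defaultdict(list)
    rejection: Dict[str, int] = {}
    for ac in annotated_calls:
        if ac.call.genotype not in (Genotype.HET, Genotype.HOM_ALT):
            continue
        if affected and ac.sample_id not in affected:
            continue
        groups[(ac.sample_id, ac.gene)].append(ac)

    zygosities: List[GeneZygosity] = []
    for (sample, gene), calls in sorted(groups.items()):
        kept = _survivors_fixed_point(calls, cfg, rejection)
        if kept:
            zygosities.append(resolve_gene_zygosity(kept))

    enrichment_results = _run_enrichment(zygosities, pedigree, cfg)
    if cfg.require_enrichment:
        significant = {
            r.variant_key for r in enrichment_results if r.significant
        }
        filtered = []
        for z in zygosities:
            kept = [c for c in z.calls if c.key in significant]
            if kept:
                filtered.append(resolve_gene_zygosity(kept))
        zygosities = filtered

    findings_by_sample: Dict[str, List[CategorizedFinding]] = defaultdict(list)
    pass_counts = {"category1": 0, "category2": 0, "category3": 0}
    staged = {1: [], 2: [], 3: []}
    for z in zygosities:
        finding = classify(z, panel1, panel2)
        if finding is None:
            continue
        staged[finding.category].append(finding)
    # three passes in protocol order; pass 3 runs cohort-wide
    for category in (1, 2, 3):
        for finding in staged[category]:
            if category == 3:
                finding = flag_other_phenotype(finding, other_phenotype_genes)
            findings_by_sample[finding.sample_id].append(finding)
            pass_counts[f"category{category}"] += 1

    return ScreenResult(
        dict(findings_by_sample), rejection, pass_counts, enrichment_results
    )


def _run_enrichment(zygosities, pedigree, cfg):
    """Cohort-vs-population allele-count Fisher tests for surviving variants."""
    affected = [i for i in pedigree if i.affected]
    cohort_an = 2 * len(affected) if affected else None
    if not cohort_an:
        return []
    ac_by_key: Dict[tuple, int] = defaultdict(int)
    ann_by_key = {}
    for z in zygosities:
        for c in z.calls:
            ac_by_key[c.key] += 2 if c.call.genotype == Genotype.HOM_ALT else 1
            ann_by_key[c.key] = c.annotation
    tests = []
    for key in sorted(ac_by_key):
        ann = ann_by_key[key]
        if ann.gnomad_ac is not None and ann.gnomad_an is not None:
            pac, pan = ann.gnomad_ac, ann.gnomad_an
        else:
            pan = cfg.population_an
            pac = round(ann.gnomad_af * pan)
        tests.append((key, min(ac_by_key[key], cohort_an), cohort_an, pac, pan))
    return variant_enrichment(tests, cfg)
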