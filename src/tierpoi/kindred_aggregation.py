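"""Kindred-level aggregation of per-individual findings.

A kindred-level finding requires the shared variant set to be present in
every recruited affected member; kindreds of one pass through unchanged
with segregation untestable. Findings that fail a segregation check are
flagged, never dropped.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from .models import (
    CategorizedFinding,
    Genotype,
    Individual,
    KindredFinding,
)

__all__ = ["aggregate_kindred", "check_segregation"]


def aggregate_kindred(
    findings_by_sample: Mapping[str, Sequence[CategorizedFinding]],
    pedigree: Sequence[Individual],
) -> List[KindredFinding]:
    """Intersect findings across recruited affected members of each kindred.

    Per gene, the kindred finding keeps the variants shared by every
    affected member; its zygosity is the shared zygosity class. Affected
    members with discordant zygosity for the shared variants yield
    segregation_status="inconsistent". Kindreds sharing nothing contribute
    no finding.
    """
    members_by_kindred: Dict[str, List[Individual]] = defaultdict(list)
    for ind in pedigree:
        members_by_kindred[ind.kindred_id].append(ind)

    results: List[KindredFinding] = []
    for kindred_id in sorted(members_by_kindred):
        affected = [
            i for i in members_by_kindred[kindred_id] if i.affected
        ]
        if not affected:
            continue
        per_gene: Dict[str, List[CategorizedFinding]] = defaultdict(list)
        for ind in affected:
            for f in findings_by_sample.get(ind.sample_id, []):
                per_gene[f.gene].append(f)
        for gene in sorted(per_gene):
            fs = per_gene[gene]
            carriers = {f.sample_id for f in fs}
            if carriers != {i.sample_id for i in affected}:
                continue  # not shared by every recruited affected member
            shared = set(fs[0].zygosity.variants)
            for f in fs[1:]:
                shared &= set(f.zygosity.variants)
            if not shared:
                continue
            zygs = {f.zygosity.zyg_class for f in fs}
            status = "consistent" if len(zygs) == 1 else "inconsistent"
            if len(affected) == 1:
                status = "untestable"
            rep = fs[0]
            results.append(
                KindredFinding(
                    kindred_id=kindred_id,
                    gene=gene,
                    shared_variant_keys=tuple(sorted(shared)),
                    zyg_class=rep.zygosity.zyg_class,
                    category=rep.category,
                    tier=rep.tier,
                    segregation_status=status,
                    member_ids=tuple(sorted(carriers)),
                )
            )
    return results


def check_segregation(
    kf: KindredFinding,
    unaffected_genotypes: Optional[Mapping[str, Mapping[tuple, str]]] = None,
) -> str:
    """Segregation status of a kindred finding against unaffected relatives.

    ``unaffected_genotypes`` maps unaffected sample id ->
    {variant_key: genotype}. Recessive findings (homozygous / compound
    het) are inconsistent when an unaffected member is hom_alt for the
    shared variant (or carries both compound-het alleles); dominant
    findings are inconsistent when any unaffected member carries the
    variant at all — full penetrance is assumed, which is the loggable
    assumption of this check.
    """
    if not unaffected_genotypes:
        return "untestable"
    recessive = kf.zyg_class in ("homozygous", "probable_compound_het")
    tested = False
    for gts in unaffected_genotypes.values():
        relevant = {
            k: g for k, g in gts.items() if k in set(kf.shared_variant_keys)
        }
        if not relevant:
            continue
        tested = True
        if recessive:
            if kf.zyg_class == "homozygous":
                if any(g == Genotype.HOM_ALT for g in relevant.values()):
                    return "inconsistent"
            else:
                carried = [
                    g in (Genotype.HET, Genotype.HOM_ALT)
                    for k, g in gts.items()
                    if k in set(kf.shared_variant_keys)
                ]
                if len(carried) == len(kf.shared_variant_keys) and all(carried):
                    return "inconsistent"
        else:
            if any(
                g in (Genotype.HET, Genotype.HOM_ALT) for g in relevant.values()
            ):
                return "inconsistent"
    return "consistent" if tested else "untestable"
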