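"""Zygosity resolution and inheritance-mode labeling.

Phase is never assumed: two heterozygous variants in one gene are only a
*probable* compound heterozygote unless parental genotypes prove them cis,
in which case the pair collapses to the single lower-frequency
heterozygous finding.

Label precedence, applied to an individual's (or kindred's) Category 1/2
findings only:

1. all findings homozygous                  -> AR (one or several genes;
   co-occurring homozygous recessive findings stay recessive)
2. findings in >= 2 distinct genes          -> oligogenic
3. single gene, homozygous                  -> AR
4. single gene, probable compound het       -> CH
5. single gene, heterozygous                -> AD

Category 3 findings never contribute to the label.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

from .models import AnnotatedCall, CategorizedFinding, Genotype, GeneZygosity

__all__ = [
    "resolve_gene_zygosity",
    "rarity_context",
    "label_inheritance",
    "label_from_records",
    "collapse_cis_pair",
    "LABELS",
]

LABELS = ("AR", "CH", "AD", "oligogenic")


def label_from_records(records: Iterable[tuple]) -> Optional[str]:
    """Precedence labeling over (gene, category, zyg_class) records.

    Shared by per-individual and per-kindred labeling; Category 3 records
    are ignored and None is returned when nothing remains.
    """
    core = [(g, z) for g, cat, z in records if cat in (1, 2)]
    if not core:
        return None
    genes = {g for g, _ in core}
    zygs = [z for _, z in core]
    if all(z == "homozygous" for z in zygs):
        return "AR"
    if len(genes) >= 2:
        return "oligogenic"
    order = {"homozygous": 0, "probable_compound_het": 1, "heterozygous": 2}
    z = min(zygs, key=order.__getitem__)
    return {"homozygous": "AR", "probable_compound_het": "CH", "heterozygous": "AD"}[z]


def resolve_gene_zygosity(calls: Sequence[AnnotatedCall]) -> GeneZygosity:
    """Classify one sample's calls in one gene.

    homozygous when any member call is hom_alt; probable compound het when
    >= 2 distinct het variants and no hom_alt; heterozygous for exactly one
    het variant.
    """
    calls = sorted(calls, key=lambda c: c.key)
    if not calls:
        raise ValueError("resolve_gene_zygosity requires at least one call")
    samples = {c.sample_id for c in calls}
    genes = {c.gene for c in calls}
    if len(samples) != 1 or len(genes) != 1:
        raise ValueError("calls must belong to one sample and one gene")
    keys = tuple(dict.fromkeys(c.key for c in calls))
    if any(c.call.genotype == Genotype.HOM_ALT for c in calls):
        zyg = "homozygous"
    elif len(keys) >= 2:
        zyg = "probable_compound_het"
    else:
        zyg = "heterozygous"
    return GeneZygosity(
        sample_id=calls[0].sample_id,
        gene=calls[0].gene,
        variants=keys,
        zyg_class=zyg,
        calls=tuple(calls),
    )


def rarity_context(z: GeneZygosity) -> Dict[tuple, str]:
    """Rarity context per member variant: biallelic for homozygous and
    compound-het members, monoallelic for a lone heterozygote."""
    ctx = "biallelic" if z.zyg_class in ("homozygous", "probable_compound_het") else "monoallelic"
    return {key: ctx for key in z.variants}


def collapse_cis_pair(
    z: GeneZygosity, parent_genotypes: Optional[Dict[str, Dict[tuple, str]]] = None
) -> GeneZygosity:
    """Collapse a probable compound-het pair proven cis by parental data.

    ``parent_genotypes`` maps parent sample id -> {variant_key: genotype}.
    If one parent carries every member variant (and the other carries
    none), the variants are in cis and the pair collapses to the single
    lowest-frequency heterozygous finding. Anything short of that proof
    leaves the probable compound het unchanged.
    """
    if z.zyg_class != "probable_compound_het" or not parent_genotypes:
        return z
    carriers = []
    for pid, gts in parent_genotypes.items():
        carried = {
            k for k, g in gts.items() if g in (Genotype.HET, Genotype.HOM_ALT)
        }
        carriers.append(set(z.variants) & carried)
    all_from_one = any(c == set(z.variants) for c in carriers)
    others_clean = sum(1 for c in carriers if c) <= 1
    if not (all_from_one and others_clean and len(carriers) >= 2):
        return z
    keep = min(z.calls, key=lambda c: (c.annotation.gnomad_af, c.key))
    return GeneZygosity(
        sample_id=z.sample_id,
        gene=z.gene,
        variants=(keep.key,),
        zyg_class="heterozygous",
        calls=(keep,),
    )


def label_inheritance(findings: Iterable[CategorizedFinding]) -> Optional[str]:
    """Single inheritance label for one individual's findings.

    Only Category 1/2 findings count; returns None when there are none
    (the individual is Category-3-only or finding-free).
    """
    return label_from_records(
        (f.gene, f.category, f.zygosity.zyg_class) for f in findings
    )
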