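"""Pre-categorization filter cascade.

Five independent predicates applied to every annotated call, in the order
quality -> in-silico -> rarity -> synonymous/splice -> ACMG. All stages are
always evaluated so the verdict can list every failure, but retention
requires all five. A variant flagged as an established disease variant
bypasses the in-silico and rarity stages only.

Operator conventions follow the protocol text exactly: quality and depth
thresholds are inclusive (">="), the CADD cutoff and both MAF thresholds
are strict ("> 15", "< 0.01%").
"""

from __future__ import annotations

from .models import (
    AnnotatedCall,
    Consequence,
    FilterConfig,
    FilterVerdict,
    VariantAnnotation,
    VariantCall,
)

__all__ = [
    "passes_quality",
    "insilico_deleterious",
    "passes_rarity",
    "synonymous_retention",
    "acmg_retained",
    "run_filter_cascade",
]


def passes_quality(call: VariantCall, cfg: FilterConfig) -> bool:
    """Inclusive call-quality and read-depth gate; missing values fail."""
    if call.qual is None or call.depth is None:
        return False
    return call.qual >= cfg.min_qual and call.depth >= cfg.min_depth


def insilico_deleterious(ann: VariantAnnotation, cfg: FilterConfig) -> bool:
    """2-of-3 damaging verdicts across CADD (> cutoff, strict), PolyPhen2, SIFT.

    Missing individual tool verdicts count as non-votes. An established
    disease variant passes regardless of votes.
    """
    if ann.established_pathogenic:
        return True
    votes = 0
    if ann.cadd is not None and ann.cadd > cfg.cadd_cutoff:
        votes += 1
    if ann.polyphen_damaging:
        votes += 1
    if ann.sift_deleterious:
        votes += 1
    return votes >= cfg.insilico_votes_required


def passes_rarity(
    ann: VariantAnnotation, context: str, cfg: FilterConfig
) -> bool:
    """Strict MAF threshold by zygosity context.

    ``context`` is "biallelic" (homozygous or member of a probable
    compound-het pair) or "monoallelic" (everything else). Absent from the
    population reference (af == 0) counts as novel and passes. Established
    disease variants pass regardless of frequency.
    """
    if context not in ("biallelic", "monoallelic"):
        raise ValueError(f"unknown rarity context {context!r}")
    if ann.established_pathogenic:
        return True
    threshold = cfg.maf_biallelic if context == "biallelic" else cfg.maf_monoallelic
    return ann.gnomad_af < threshold


def synonymous_retention(ann: VariantAnnotation, cfg: FilterConfig) -> bool:
    """Synonymous/intronic exclusion with splice-loss rescue.

    Non-synonymous exonic consequences pass untouched. A splice_site
    consequence is retained when splice loss is predicted (canonical-site
    variants and deeper intronic variants with a positive splice-model
    prediction both qualify). Plain intronic changes additionally require
    the position to lie within ``intronic_splice_window`` bases of the exon
    boundary; exonic synonymous changes require a positive splice
    prediction.
    """
    c = ann.consequence
    if c == Consequence.SPLICE_SITE:
        return bool(ann.splice_loss_predicted)
    if c == Consequence.INTRONIC:
        return (
            abs(ann.intron_offset) <= cfg.intronic_splice_window
            and bool(ann.splice_loss_predicted)
        )
    if c == Consequence.SYNONYMOUS:
        return bool(ann.splice_loss_predicted)
    return True


def acmg_retained(ann: VariantAnnotation) -> bool:
    """Retain pathogenic / likely pathogenic only; missing class fails."""
    return ann.acmg_class in ("P", "LP")


def run_filter_cascade(
    ac: AnnotatedCall, context: str, cfg: FilterConfig
) -> FilterVerdict:
    """Evaluate all five stages and return the full verdict."""
    ann = ac.annotation
    failed = []
    reasons = []
    bypass = False

    if not passes_quality(ac.call, cfg):
        failed.append("quality")
        reasons.append(
            f"qual={ac.call.qual} depth={ac.call.depth} below "
            f">={cfg.min_qual}/>={cfg.min_depth}"
        )
    if ann.established_pathogenic:
        bypass = True  # skips insilico and rarity
    else:
        if not insilico_deleterious(ann, cfg):
            failed.append("insilico")
            reasons.append("fewer than required damaging in-silico votes")
        if not passes_rarity(ann, context, cfg):
            failed.append("rarity")
            reasons.append(
                f"gnomad_af={ann.gnomad_af} not < threshold for {context} context"
            )
    if not synonymous_retention(ann, cfg):
        failed.append("synonymous_splice")
        reasons.append("synonymous/intronic change without splice-loss rescue")
    if not acmg_retained(ann):
        failed.append("acmg")
        reasons.append(f"ACMG class {ann.acmg_class!r} not in (P, LP)")

    return FilterVerdict(
        passed=not failed,
        failed_stages=tuple(failed),
        bypass_used=bypass,
        reasons=tuple(reasons),
    )
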