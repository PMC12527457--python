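"""Cohort-level summaries: detection rates, inheritance-mode proportions,
familial-vs-sporadic contrasts.

Sporadic summaries count individuals; familial summaries count kindreds;
the merged summary counts "entities" (one sporadic individual or one
familial kindred each). Proportions are kept at full precision and rounded
half-up to one decimal place only for display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

from .enrichment_stats import fisher_exact_two_tailed
from .inheritance import LABELS, label_from_records
from .models import (
    CategorizedFinding,
    FilterConfig,
    Individual,
    KindredFinding,
    variant_key_str,
)

__all__ = ["CohortSummary", "summarize", "compare_subcohorts", "render_report", "pct"]


def pct(count: int, denom: int, digits: int = 1) -> float:
    """Percentage rounded half-up, matching tabular presentation style."""
    if denom == 0:
        return 0.0
    q = Decimal(count) * 100 / Decimal(denom)
    return float(q.quantize(Decimal(10) ** -digits, rounding=ROUND_HALF_UP))


@dataclass
class LevelSummary:
    """Counts for one summary level (individuals, kindreds, or entities)."""

    n_total: int
    n_with_cat12: int
    n_cat1: int
    n_cat2_only: int
    n_cat3_candidates: int
    label_counts: Dict[str, int]

    def as_dict(self) -> dict:
        d = {
            "n_total": self.n_total,
            "with_category_1_or_2": self.n_with_cat12,
            "with_category_1_or_2_pct": pct(self.n_with_cat12, self.n_total),
            "category_1": self.n_cat1,
            "category_1_pct": pct(self.n_cat1, self.n_total),
            "category_2_only": self.n_cat2_only,
            "category_2_only_pct": pct(self.n_cat2_only, self.n_total),
            "category_3_candidates": self.n_cat3_candidates,
        }
        for label in LABELS:
            d[f"label_{label}"] = self.label_counts.get(label, 0)
            d[f"label_{label}_pct_of_total"] = pct(
                self.label_counts.get(label, 0), self.n_total
            )
            d[f"label_{label}_pct_of_found"] = pct(
                self.label_counts.get(label, 0), self.n_with_cat12
            )
        return d


@dataclass
class Comparison:
    description: str
    table: list
    p_value: float
    significant: bool


@dataclass
class CohortSummary:
    sporadic: LevelSummary
    familial: LevelSummary
    merged: LevelSummary
    distinct_gene_count: int
    variant_count: int
    comparisons: List[Comparison] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "sporadic_individuals": self.sporadic.as_dict(),
            "familial_kindreds": self.familial.as_dict(),
            "merged_entities": self.merged.as_dict(),
            "distinct_category_1_or_2_genes": self.distinct_gene_count,
            "category_1_or_2_variant_count": self.variant_count,
            "comparisons": [
                {
                    "description": c.description,
                    "table": c.table,
                    "p_value": c.p_value,
                    "significant": c.significant,
                }
                for c in self.comparisons
            ],
        }


def _entity_records(findings) -> List[tuple]:
    return [(f.gene, f.category, _zyg(f)) for f in findings]


def _zyg(f) -> str:
    z = getattr(f, "zyg_class", None)
    if z is not None:
        return z
    zy = f.zygosity
    return zy if isinstance(zy, str) else zy.zyg_class


def _has_unflagged_cat3(findings) -> bool:
    return any(
        f.category == 3 and not getattr(f, "other_phenotype_flag", False)
        for f in findings
    )


def _level_summary(entities: Mapping[str, Sequence], n_total: int) -> LevelSummary:
    """``entities`` maps entity id -> its findings (individual or kindred level)."""
    n_with = n_cat1 = n_cat2_only = n_cat3 = 0
    label_counts: Dict[str, int] = {label: 0 for label in LABELS}
    for _, findings in sorted(entities.items()):
        cats = {f.category for f in findings}
        has1 = 1 in cats
        has2 = 2 in cats
        if has1 or has2:
            n_with += 1
        if has1:
            n_cat1 += 1
        elif has2:
            n_cat2_only += 1
        if _has_unflagged_cat3(findings):
            n_cat3 += 1
        label = label_from_records(_entity_records(findings))
        if label is not None:
            label_counts[label] += 1
    return LevelSummary(
        n_total=n_total,
        n_with_cat12=n_with,
        n_cat1=n_cat1,
        n_cat2_only=n_cat2_only,
        n_cat3_candidates=n_cat3,
        label_counts=label_counts,
    )


def summarize(
    findings_by_sample: Mapping[str, Sequence[CategorizedFinding]],
    kindred_findings: Sequence[KindredFinding],
    pedigree: Sequence[Individual],
    cfg: Optional[FilterConfig] = None,
) -> CohortSummary:
    """Full cohort summary over individual, kindred and merged entity levels."""
    cfg = cfg or FilterConfig()
    affected = [i for i in pedigree if i.affected]
    if not affected:
        raise ValueError("empty cohort: no affected individuals in pedigree")

    sporadic_inds = [i for i in affected if i.subcohort == "sporadic"]
    familial_kindreds = sorted(
        {i.kindred_id for i in affected if i.subcohort == "familial"}
    )

    sporadic_entities = {
        i.sample_id: list(findings_by_sample.get(i.sample_id, []))
        for i in sporadic_inds
    }
    kf_by_kindred: Dict[str, List[KindredFinding]] = {
        k: [] for k in familial_kindreds
    }
    for kf in kindred_findings:
        if kf.kindred_id in kf_by_kindred:
            kf_by_kindred[kf.kindred_id].append(kf)

    sporadic = _level_summary(sporadic_entities, len(sporadic_inds))
    familial = _level_summary(kf_by_kindred, len(familial_kindreds))
    merged_entities: Dict[str, Sequence] = {}
    merged_entities.update({f"I:{k}": v for k, v in sporadic_entities.items()})
    merged_entities.update({f"K:{k}": v for k, v in kf_by_kindred.items()})
    merged = _level_summary(
        merged_entities, len(sporadic_inds) + len(familial_kindreds)
    )

    genes = set()
    variant_keys = set()
    for findings in sporadic_entities.values():
        for f in findings:
            if f.category in (1, 2):
                genes.add(f.gene)
                variant_keys.update(f.zygosity.variants)
    for kfs in kf_by_kindred.values():
        for kf in kfs:
            if kf.category in (1, 2):
                genes.add(kf.gene)
                variant_keys.update(kf.shared_variant_keys)

    summary = CohortSummary(
        sporadic=sporadic,
        familial=familial,
        merged=merged,
        distinct_gene_count=len(genes),
        variant_count=len(variant_keys),
    )
    summary.comparisons = compare_subcohorts(summary, cfg)
    return summary


def compare_subcohorts(
    summary: CohortSummary, cfg: Optional[FilterConfig] = None
) -> List[Comparison]:
    """Entity-level familial-vs-sporadic Fisher contrasts.

    Each contrast is mode (or category) membership vs subcohort, with
    subcohort totals as denominators. Degenerate tables are skipped.
    """
    cfg = cfg or FilterConfig()
    fam, spo = summary.familial, summary.sporadic
    specs = [
        (
            "homozygous (AR) findings, familial kindreds vs sporadic individuals",
            fam.label_counts.get("AR", 0),
            fam.n_total,
            spo.label_counts.get("AR", 0),
            spo.n_total,
        ),
        (
            "single heterozygous (AD) findings, familial vs sporadic",
            fam.label_counts.get("AD", 0),
            fam.n_total,
            spo.label_counts.get("AD", 0),
            spo.n_total,
        ),
        (
            "Category 1 findings, familial vs sporadic",
            fam.n_cat1,
            fam.n_total,
            spo.n_cat1,
            spo.n_total,
        ),
    ]
    out = []
    for desc, a, na, c, nc in specs:
        table = [[a, na - a], [c, nc - c]]
        if na == 0 or nc == 0 or (a + c == 0) or (na - a + nc - c == 0):
            continue  # degenerate margins
        p = fisher_exact_two_tailed(table)
        out.append(Comparison(desc, table, p, p < cfg.summary_alpha))
    return out


def render_report(
    summary: CohortSummary,
    out_dir,
    findings_by_sample: Optional[Mapping[str, Sequence[CategorizedFinding]]] = None,
    kindred_findings: Optional[Sequence[KindredFinding]] = None,
) -> Dict[str, Path]:
    """Write summary.json plus TSV views; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    p = out_dir / "summary.json"
    p.write_text(json.dumps(summary.as_dict(), indent=2) + "\n")
    paths["summary.json"] = p

    rows = ["level\tmetric\tcount\tdenominator\tpercent"]
    for level_name, level in (
        ("sporadic_individuals", summary.sporadic),
        ("familial_kindreds", summary.familial),
        ("merged_entities", summary.merged),
    ):
        for metric, count in (
            ("with_category_1_or_2", level.n_with_cat12),
            ("category_1", level.n_cat1),
            ("category_2_only", level.n_cat2_only),
            ("category_3_candidates", level.n_cat3_candidates),
        ):
            rows.append(
                f"{level_name}\t{metric}\t{count}\t{level.n_total}\t"
                f"{pct(count, level.n_total)}"
            )
    p = out_dir / "summary_by_category.tsv"
    p.write_text("\n".join(rows) + "\n")
    paths["summary_by_category.tsv"] = p

    rows = ["level\tlabel\tcount\tdenominator_found\tpercent_of_found"]
    for level_name, level in (
        ("sporadic_individuals", summary.sporadic),
        ("familial_kindreds", summary.familial),
        ("merged_entities", summary.merged),
    ):
        for label in LABELS:
            count = level.label_counts.get(label, 0)
            rows.append(
                f"{level_name}\t{label}\t{count}\t{level.n_with_cat12}\t"
                f"{pct(count, level.n_with_cat12)}"
            )
    p = out_dir / "summary_by_mode.tsv"
    p.write_text("\n".join(rows) + "\n")
    paths["summary_by_mode.tsv"] = p

    rows = ["description\ta\tb\tc\td\tp_value\tsignificant"]
    for c in summary.comparisons:
        (a, b), (cc, d) = c.table
        rows.append(
            f"{c.description}\t{a}\t{b}\t{cc}\t{d}\t{c.p_value:.6g}\t{c.significant}"
        )
    p = out_dir / "comparisons.tsv"
    p.write_text("\n".join(rows) + "\n")
    paths["comparisons.tsv"] = p

    if kindred_findings is not None:
        rows = [
            "kindred_id\tgene\tvariants\tzygosity\tcategory\ttier\tsegregation"
        ]
        for kf in kindred_findings:
            keys = ";".join(variant_key_str(k) for k in kf.shared_variant_keys)
            rows.append(
                f"{kf.kindred_id}\t{kf.gene}\t{keys}\t{kf.zyg_class}\t"
                f"{kf.category}\t{kf.tier}\t{kf.segregation_status}"
            )
        p = out_dir / "kindred_findings.tsv"
        p.write_text("\n".join(rows) + "\n")
        paths["kindred_findings.tsv"] = p

    return paths
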