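"""End-to-end orchestration: screen -> aggregate -> summarize.

The functions here are thin compositions of the component modules and are
what the command-line interface and the reproduction script call.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import yaml

from .cohort_report import CohortSummary, render_report, summarize
from .io_formats import FindingRecord, write_findings, write_run_log
from .kindred_aggregation import aggregate_kindred
from .models import (
    AnnotatedCall,
    CategorizedFinding,
    FilterConfig,
    GenePanelEntry,
    Individual,
    KindredFinding,
)
from .tier_classifier import ScreenResult, run_tiered_screen
from .inheritance import label_inheritance

__all__ = [
    "AnalysisResult",
    "analyze",
    "analyze_bundle",
    "finding_records",
    "summarize_records",
    "load_filter_config",
    "build_run_log",
]


@dataclass
class AnalysisResult:
    screen: ScreenResult
    labels_by_sample: Dict[str, Optional[str]]
    kindred_findings: List[KindredFinding]
    summary: CohortSummary

    @property
    def findings_by_sample(self) -> Dict[str, List[CategorizedFinding]]:
        return self.screen.findings_by_sample


def analyze(
    annotated_calls: Sequence[AnnotatedCall],
    panel1: Mapping[str, GenePanelEntry],
    panel2: Mapping[str, GenePanelEntry],
    pedigree: Sequence[Individual],
    cfg: Optional[FilterConfig] = None,
    other_phenotype: Optional[Mapping[str, str]] = None,
) -> AnalysisResult:
    """Full pipeline over in-memory inputs."""
    cfg = cfg or FilterConfig()
    screen = run_tiered_screen(
        annotated_calls, panel1, panel2, pedigree, cfg, other_phenotype
    )
    labels = {
        sid: label_inheritance(fs)
        for sid, fs in sorted(screen.findings_by_sample.items())
    }
    kindred_findings = aggregate_kindred(screen.findings_by_sample, pedigree)
    summary = summarize(screen.findings_by_sample, kindred_findings, pedigree, cfg)
    return AnalysisResult(
        screen=screen,
        labels_by_sample=labels,
        kindred_findings=kindred_findings,
        summary=summary,
    )


def analyze_bundle(bundle, cfg: Optional[FilterConfig] = None) -> AnalysisResult:
    """Run the pipeline over a :class:`~tierpoi.synthetic_data.CohortBundle`."""
    return analyze(
        bundle.annotated_calls(),
        bundle.panel1,
        bundle.panel2,
        bundle.pedigree,
        cfg,
        bundle.other_phenotype,
    )


def finding_records(
    result: AnalysisResult, pedigree: Sequence[Individual]
) -> List[FindingRecord]:
    kindred_of = {i.sample_id: i.kindred_id for i in pedigree}
    records = []
    for sid in sorted(result.findings_by_sample):
        label = result.labels_by_sample.get(sid)
        for f in result.findings_by_sample[sid]:
            records.append(
                FindingRecord(
                    sample_id=sid,
                    kindred_id=kindred_of.get(sid, sid),
                    gene=f.gene,
                    variant_keys=f.zygosity.variants,
                    zygosity=f.zygosity.zyg_class,
                    category=f.category,
                    tier=f.tier,
                    inheritance_label=label or "",
                    reroute_reason=f.reroute_reason,
                    other_phenotype_flag=f.other_phenotype_flag,
                )
            )
    return records


class _RecordZygosity:
    """Adapter giving file-backed finding records the zygosity interface."""

    __slots__ = ("variants", "zyg_class")

    def __init__(self, variants, zyg_class):
        self.variants = tuple(variants)
        self.zyg_class = zyg_class


class _RecordView:
    __slots__ = ("sample_id", "gene", "category", "tier", "zygosity",
                 "other_phenotype_flag", "reroute_reason")

    def __init__(self, r: FindingRecord):
        self.sample_id = r.sample_id
        self.gene = r.gene
        self.category = r.category
        self.tier = r.tier
        self.zygosity = _RecordZygosity(r.variant_keys, r.zygosity)
        self.other_phenotype_flag = r.other_phenotype_flag
        self.reroute_reason = r.reroute_reason


def summarize_records(
    records: Sequence[FindingRecord],
    pedigree: Sequence[Individual],
    cfg: Optional[FilterConfig] = None,
) -> CohortSummary:
    """Recompute the cohort summary from a findings report file."""
    by_sample: Dict[str, List[_RecordView]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(_RecordView(r))
    kindred_findings = aggregate_kindred(by_sample, pedigree)
    return summarize(by_sample, kindred_findings, pedigree, cfg)


def load_filter_config(path: Optional[str]) -> FilterConfig:
    if path is None:
        return FilterConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(FilterConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return FilterConfig(**data)


def build_run_log(
    cfg: FilterConfig,
    inputs: Mapping[str, Optional[str]],
    result: AnalysisResult,
    seed: Optional[int] = None,
    warnings: Sequence[str] = (),
) -> dict:
    digests = {}
    for name, p in inputs.items():
        if p is None:
            continue
        h = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        digests[name] = {"path": str(p), "sha256": h}
    return {
        "config": dataclasses.asdict(cfg),
        "inputs": digests,
        "stage_rejections": result.screen.rejection_counts,
        "pass_counts": result.screen.pass_counts,
        "warnings": list(warnings),
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
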