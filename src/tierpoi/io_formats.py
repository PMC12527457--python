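"""Readers and writers for every external representation the pipeline touches.

Formats:

* VCF v4.x (plain or bgzipped) via pysam; multi-allelic records are
  decomposed into one call per sample per alt allele, positions stay
  1-based.
* Pedigree: whitespace-delimited 8-column PED dialect
  ``kindred_id sample_id father_id mother_id sex affected subcohort
  consanguineous`` with an optional ninth column ``external_affected``
  (1 when a single-recruited kindred is linked to unrecruited affected
  relatives). ``affected`` uses PED phenotype coding (2 = affected).
* Annotation and gene-panel tables: TSV with a declared header.
* Findings report: TSV, round-trippable field for field.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

from .models import (
    AnnotatedCall,
    GenePanelEntry,
    Genotype,
    Individual,
    VariantAnnotation,
    VariantCall,
)

logger = logging.getLogger("tierpoi")

__all__ = [
    "read_vcf",
    "read_pedigree",
    "read_gene_panel",
    "read_annotation_table",
    "read_other_phenotype_list",
    "join_annotations",
    "FindingRecord",
    "write_findings",
    "read_findings",
    "write_run_log",
]


def read_vcf(
    path, known_samples: Optional[Iterable[str]] = None
) -> Iterator[VariantCall]:
    """Stream one VariantCall per sample per alt allele from a VCF.

    A genotype containing the alt allele twice maps to hom_alt, once to
    het; ``./.`` and non-diploid genotypes map to missing (the cohort is
    46,XX, so no hemizygosity rule is needed). Samples absent from
    ``known_samples`` are retained with a warning.
    """
    import pysam

    known = set(known_samples) if known_samples is not None else None
    with pysam.VariantFile(str(path)) as vf:
        if known is not None:
            for s in vf.header.samples:
                if s not in known:
                    logger.warning(
                        "sample %s in VCF absent from pedigree; records retained", s
                    )
        record_no = 0
        try:
            for rec in vf:
                record_no += 1
                alts = rec.alts or ()
                for sample_name, sample in rec.samples.items():
                    gt = sample.get("GT")
                    depth = sample.get("DP")
                    if depth is None:
                        depth = rec.info.get("DP")
                    for alt_index, alt in enumerate(alts, start=1):
                        genotype = _genotype_for_alt(gt, alt_index, rec, sample_name)
                        yield VariantCall(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            qual=rec.qual,
                            depth=depth,
                            sample_id=sample_name,
                            genotype=genotype,
                        )
        except (ValueError, OSError) as exc:
            raise ValueError(
                f"malformed VCF record near data record {record_no + 1} "
                f"of {path}: {exc}"
            ) from exc


def _genotype_for_alt(gt, alt_index: int, rec, sample_name: str) -> str:
    if gt is None or all(a is None for a in gt):
        return Genotype.MISSING
    if len(gt) != 2 or any(a is None for a in gt):
        logger.warning(
            "non-diploid genotype %s for %s at %s:%s treated as missing",
            gt,
            sample_name,
            rec.chrom,
            rec.pos,
        )
        return Genotype.MISSING
    count = sum(1 for a in gt if a == alt_index)
    if count == 2:
        return Genotype.HOM_ALT
    if count == 1:
        return Genotype.HET
    return Genotype.HOM_REF


_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


def _parse_bool(token: str, *, where: str) -> bool:
    t = token.strip().lower()
    if t in _TRUTHY:
        return True
    if t in _FALSY:
        return False
    raise ValueError(f"cannot parse boolean {token!r} in {where}")


def read_pedigree(path) -> List[Individual]:
    """Parse the extended PED dialect; validates referential integrity."""
    individuals: List[Individual] = []
    seen = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 8:
                raise ValueError(
                    f"{path}:{line_no}: expected >=8 columns, got {len(parts)}"
                )
            kindred, sample, father, mother, _sex, pheno, subcohort = parts[:7]
            consang = parts[7]
            external = parts[8] if len(parts) > 8 else "0"
            if sample in seen:
                raise ValueError(f"{path}:{line_no}: duplicate sample_id {sample}")
            seen.add(sample)
            if subcohort not in ("familial", "sporadic", "relative"):
                raise ValueError(
                    f"{path}:{line_no}: unknown subcohort token {subcohort!r}"
                )
            individuals.append(
                Individual(
                    sample_id=sample,
                    kindred_id=kindred,
                    affected=pheno.strip() == "2",
                    subcohort=subcohort,
                    consanguineous=_parse_bool(consang, where=f"{path}:{line_no}"),
                    father_id="" if father in ("0", ".") else father,
                    mother_id="" if mother in ("0", ".") else mother,
                    external_affected=_parse_bool(
                        external, where=f"{path}:{line_no}"
                    ),
                )
            )
    ids = {i.sample_id for i in individuals}
    for ind in individuals:
        for pid in (ind.father_id, ind.mother_id):
            if pid and pid not in ids:
                logger.warning(
                    "parent %s of %s not present in pedigree (declared external)",
                    pid,
                    ind.sample_id,
                )
    return individuals


def read_gene_panel(path) -> List[GenePanelEntry]:
    """TSV columns: gene, category, tier, expected_inheritance, source_note.

    ``expected_inheritance`` is a comma-joined subset of
    {biallelic, monoallelic}; tier "none" for category 2.
    """
    entries: Dict[str, GenePanelEntry] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene", "category", "tier", "expected_inheritance"}
        if not required <= set(reader.fieldnames or []):
            raise ValueError(
                f"{path}: panel header must contain {sorted(required)}"
            )
        for row in reader:
            models = frozenset(
                m.strip()
                for m in (row.get("expected_inheritance") or "").split(",")
                if m.strip()
            )
            entry = GenePanelEntry(
                gene=row["gene"].strip(),
                category=int(row["category"]),
                tier=(row.get("tier") or "none").strip() or "none",
                expected_inheritance=models,
                source_note=(row.get("source_note") or "").strip(),
            )
            prev = entries.get(entry.gene)
            if prev is not None and prev != entry:
                raise ValueError(
                    f"{path}: duplicate panel gene {entry.gene} with "
                    "conflicting entries"
                )
            entries[entry.gene] = entry
    return list(entries.values())


_ANN_FIELDS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "intron_offset",
    "gnomad_af",
    "gnomad_ac",
    "gnomad_an",
    "cadd",
    "polyphen_damaging",
    "sift_deleterious",
    "acmg_class",
    "splice_loss_predicted",
    "established_pathogenic",
]


def _opt(row, field, conv):
    v = (row.get(field) or "").strip()
    if v in ("", ".", "NA"):
        return None
    return conv(v)


def read_annotation_table(path) -> List[VariantAnnotation]:
    """Read per-allele annotations keyed by (chrom, pos, ref, alt)."""
    out: List[VariantAnnotation] = []
    seen = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = {"chrom", "pos", "ref", "alt", "gene"} - set(
            reader.fieldnames or []
        )
        if missing:
            raise ValueError(f"{path}: annotation header lacks {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            key = (
                row["chrom"].strip(),
                int(row["pos"]),
                row["ref"].strip(),
                row["alt"].strip(),
            )
            if key in seen:
                raise ValueError(f"{path}:{line_no}: duplicate annotation key {key}")
            seen.add(key)
            out.append(
                VariantAnnotation(
                    variant_key=key,
                    gene=row["gene"].strip(),
                    transcript=(row.get("transcript") or "").strip(),
                    hgvs_c=(row.get("hgvs_c") or "").strip(),
                    hgvs_p=(row.get("hgvs_p") or "").strip(),
                    consequence=(row.get("consequence") or "missense").strip(),
                    intron_offset=int(row.get("intron_offset") or 0),
                    gnomad_af=float(row.get("gnomad_af") or 0.0),
                    gnomad_ac=_opt(row, "gnomad_ac", int),
                    gnomad_an=_opt(row, "gnomad_an", int),
                    cadd=_opt(row, "cadd", float),
                    polyphen_damaging=_opt(
                        row, "polyphen_damaging", lambda v: v.lower() in _TRUTHY
                    ),
                    sift_deleterious=_opt(
                        row, "sift_deleterious", lambda v: v.lower() in _TRUTHY
                    ),
                    acmg_class=_opt(row, "acmg_class", str),
                    splice_loss_predicted=_opt(
                        row, "splice_loss_predicted", lambda v: v.lower() in _TRUTHY
                    ),
                    established_pathogenic=_parse_bool(
                        row.get("established_pathogenic") or "0",
                        where=f"{path}:{line_no}",
                    ),
                )
            )
    return out


def read_other_phenotype_list(path) -> Dict[str, str]:
    """TSV columns: gene, phenotype."""
    out: Dict[str, str] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["gene"].strip()] = (row.get("phenotype") or "").strip()
    return out


def join_annotations(
    calls: Iterable[VariantCall],
    annotations: Iterable[VariantAnnotation],
) -> Tuple[List[AnnotatedCall], List[VariantCall]]:
    """Exact-key join; unannotated calls go to the sink list."""
    by_key: Dict[tuple, VariantAnnotation] = {}
    for ann in annotations:
        if ann.variant_key in by_key:
            raise ValueError(f"duplicate annotation key {ann.variant_key}")
        by_key[ann.variant_key] = ann
    annotated: List[AnnotatedCall] = []
    sink: List[VariantCall] = []
    for call in calls:
        ann = by_key.get(call.key)
        if ann is None:
            sink.append(call)
        else:
            annotated.append(AnnotatedCall(call=call, annotation=ann))
    if sink:
        logger.info("%d calls lacked an annotation and were sunk", len(sink))
    return annotated, sink


@dataclass(frozen=True)
class FindingRecord:
    """Flat, file-backed view of one per-individual finding."""

    sample_id: str
    kindred_id: str
    gene: str
    variant_keys: tuple
    zygosity: str
    category: int
    tier: str
    inheritance_label: str
    reroute_reason: str = "none"
    other_phenotype_flag: bool = False


_FINDING_HEADER = [
    "sample_id",
    "kindred_id",
    "gene",
    "variant_keys",
    "zygosity",
    "category",
    "tier",
    "inheritance_label",
    "reroute_reason",
    "other_phenotype_flag",
]


def write_findings(records: Sequence[FindingRecord], path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_FINDING_HEADER)
        for r in records:
            keys = ";".join("|".join(map(str, k)) for k in r.variant_keys)
            w.writerow(
                [
                    r.sample_id,
                    r.kindred_id,
                    r.gene,
                    keys,
                    r.zygosity,
                    r.category,
                    r.tier,
                    r.inheritance_label,
                    r.reroute_reason,
                    int(r.other_phenotype_flag),
                ]
            )
    return path


def read_findings(path) -> List[FindingRecord]:
    out: List[FindingRecord] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            keys = tuple(
                (
                    lambda p: (p[0], int(p[1]), p[2], p[3])
                )(token.split("|"))
                for token in row["variant_keys"].split(";")
                if token
            )
            out.append(
                FindingRecord(
                    sample_id=row["sample_id"],
                    kindred_id=row["kindred_id"],
                    gene=row["gene"],
                    variant_keys=keys,
                    zygosity=row["zygosity"],
                    category=int(row["category"]),
                    tier=row["tier"],
                    inheritance_label=row["inheritance_label"],
                    reroute_reason=row["reroute_reason"],
                    other_phenotype_flag=bool(int(row["other_phenotype_flag"])),
                )
            )
    return out


def write_run_log(log: Mapping, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dict(log), indent=2, sort_keys=True) + "\n")
    return path
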