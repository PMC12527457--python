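"""Domain types shared across the prioritization pipeline.

Positions are 1-based throughout (VCF convention); allele frequencies are
fractions in [0, 1]; MAF thresholds in :class:`FilterConfig` are therefore
fractions too (0.01% == 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "Genotype",
    "Consequence",
    "VariantCall",
    "VariantAnnotation",
    "AnnotatedCall",
    "Individual",
    "GenePanelEntry",
    "FilterConfig",
    "FilterVerdict",
    "GeneZygosity",
    "CategorizedFinding",
    "KindredFinding",
    "EnrichmentResult",
    "variant_key_str",
]


class Genotype:
    """Diploid genotype of one sample for one alt allele."""

    HET = "het"
    HOM_ALT = "hom_alt"
    HOM_REF = "hom_ref"
    MISSING = "missing"

    ALL = frozenset({HET, HOM_ALT, HOM_REF, MISSING})


class Consequence:
    """Coarse functional consequence classes used by the filter cascade."""

    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    UTR = "utr"
    OTHER = "other"

    ALL = frozenset(
        {
            MISSENSE,
            STOP_GAIN,
            FRAMESHIFT,
            INFRAME_INDEL,
            SPLICE_SITE,
            SYNONYMOUS,
            INTRONIC,
            UTR,
            OTHER,
        }
    )
    # classes that carry a non-zero distance from the nearest exon boundary
    INTRON_BEARING = frozenset({SPLICE_SITE, INTRONIC})


def variant_key_str(key: tuple) -> str:
    """Render a (chrom, pos, ref, alt) key as ``chrom:pos:ref:alt``."""
    return "{}:{}:{}:{}".format(*key)


@dataclass(frozen=True)
class VariantCall:
    """One genotyped alt allele of one sample at one site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: Optional[float]
    depth: Optional[int]
    sample_id: str
    genotype: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if self.genotype not in Genotype.ALL:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.qual is not None and self.qual < 0:
            raise ValueError("qual must be >= 0")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class VariantAnnotation:
    """Functional, population, in-silico and clinical annotations for one allele.

    ``established_pathogenic`` marks a variant with a well-established
    relationship to the disease; such variants bypass the in-silico and
    rarity stages of the cascade (they still need call quality, the
    synonymous/splice rule and a P/LP class).
    """

    variant_key: tuple
    gene: str
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: str = Consequence.MISSENSE
    intron_offset: int = 0
    gnomad_af: float = 0.0
    gnomad_ac: Optional[int] = None
    gnomad_an: Optional[int] = None
    cadd: Optional[float] = None
    polyphen_damaging: Optional[bool] = None
    sift_deleterious: Optional[bool] = None
    acmg_class: Optional[str] = None  # P, LP, VUS, LB, B or None
    splice_loss_predicted: Optional[bool] = None
    established_pathogenic: bool = False

    def __post_init__(self):
        if self.consequence not in Consequence.ALL:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if not 0.0 <= self.gnomad_af <= 1.0:
            raise ValueError(f"gnomad_af out of [0,1]: {self.gnomad_af}")
        if (
            self.gnomad_ac is not None
            and self.gnomad_an is not None
            and self.gnomad_ac > self.gnomad_an
        ):
            raise ValueError("gnomad_ac > gnomad_an")
        if self.acmg_class is not None and self.acmg_class not in {
            "P",
            "LP",
            "VUS",
            "LB",
            "B",
        }:
            raise ValueError(f"unknown ACMG class {self.acmg_class!r}")
        if (
            self.intron_offset != 0
            and self.consequence not in Consequence.INTRON_BEARING
        ):
            raise ValueError(
                "intron_offset must be 0 for exonic consequence "
                f"{self.consequence!r}"
            )


@dataclass(frozen=True)
class AnnotatedCall:
    """A call joined with its single matching annotation."""

    call: VariantCall
    annotation: VariantAnnotation

    def __post_init__(self):
        if self.call.key != self.annotation.variant_key:
            raise ValueError(
                f"annotation key {self.annotation.variant_key} does not match "
                f"call key {self.call.key}"
            )

    @property
    def key(self) -> tuple:
        return self.call.key

    @property
    def gene(self) -> str:
        return self.annotation.gene

    @property
    def sample_id(self) -> str:
        return self.call.sample_id


SUBCOHORTS = frozenset({"familial", "sporadic", "relative"})


@dataclass(frozen=True)
class Individual:
    sample_id: str
    kindred_id: str
    affected: bool
    subcohort: str  # familial | sporadic | relative
    consanguineous: bool = False
    father_id: str = ""
    mother_id: str = ""
    # kindred recruited only one member but further affected relatives exist
    external_affected: bool = False

    def __post_init__(self):
        if self.subcohort not in SUBCOHORTS:
            raise ValueError(f"unknown subcohort {self.subcohort!r}")


TIERS = frozenset({"green", "amber", "red", "none"})
INHERITANCE_MODELS = frozenset({"biallelic", "monoallelic"})


@dataclass(frozen=True)
class GenePanelEntry:
    gene: str
    category: int  # 1 or 2
    tier: str = "none"
    expected_inheritance: frozenset = frozenset()
    source_note: str = ""

    def __post_init__(self):
        if self.category not in (1, 2):
            raise ValueError("panel category must be 1 or 2")
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.category == 1:
            if self.tier == "none":
                raise ValueError(f"category 1 gene {self.gene} requires a tier")
            if not self.expected_inheritance:
                raise ValueError(
                    f"category 1 gene {self.gene} requires expected inheritance"
                )
        else:
            if self.tier != "none":
                raise ValueError(f"category 2 gene {self.gene} must not carry a tier")
        if not set(self.expected_inheritance) <= INHERITANCE_MODELS:
            raise ValueError(
                f"unknown inheritance model(s) {set(self.expected_inheritance)}"
            )


@dataclass(frozen=True)
class FilterConfig:
    """All tunable thresholds of the cascade and the enrichment test.

    Defaults follow the study protocol: call quality >=20, depth >=10
    (inclusive); CADD strictly >15; 2-of-3 in-silico votes; gnomAD MAF
    strictly <0.01% for biallelic and <0.005% for monoallelic context;
    splice retention window 7 intronic bases; BH-adjusted Fisher cutoffs
    1e-4 (per-variant enrichment) and 0.05 (cohort summaries).
    """

    min_qual: float = 20.0
    min_depth: int = 10
    cadd_cutoff: float = 15.0
    insilico_votes_required: int = 2
    maf_biallelic: float = 1e-4
    maf_monoallelic: float = 5e-5
    intronic_splice_window: int = 7
    enrichment_alpha_adjusted: float = 1e-4
    summary_alpha: float = 0.05
    require_enrichment: bool = False
    population_an: int = 1_600_000

    def __post_init__(self):
        for name in (
            "min_qual",
            "min_depth",
            "cadd_cutoff",
            "insilico_votes_required",
            "maf_biallelic",
            "maf_monoallelic",
            "intronic_splice_window",
            "enrichment_alpha_adjusted",
            "summary_alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.maf_monoallelic > self.maf_biallelic:
            raise ValueError("maf_monoallelic must be <= maf_biallelic")

    def with_overrides(self, **kwargs) -> "FilterConfig":
        return replace(self, **kwargs)


STAGES = ("quality", "insilico", "rarity", "synonymous_splice", "acmg")


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    failed_stages: tuple = ()
    bypass_used: bool = False
    reasons: tuple = ()

    def __post_init__(self):
        if self.passed != (len(self.failed_stages) == 0):
            raise ValueError("passed must equal failed_stages being empty")
        for s in self.failed_stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")


ZYG_CLASSES = ("homozygous", "probable_compound_het", "heterozygous")


@dataclass(frozen=True)
class GeneZygosity:
    sample_id: str
    gene: str
    variants: tuple  # tuple of variant keys
    zyg_class: str
    calls: tuple = ()  # the member AnnotatedCalls, in variant-key order

    def __post_init__(self):
        if self.zyg_class not in ZYG_CLASSES:
            raise ValueError(f"unknown zygosity class {self.zyg_class!r}")
        if not self.variants:
            raise ValueError("GeneZygosity requires at least one variant")


@dataclass(frozen=True)
class CategorizedFinding:
    zygosity: GeneZygosity
    category: int  # 1, 2 or 3
    tier: str = "none"
    reroute_reason: str = "none"  # none | unexpected_inheritance
    other_phenotype_flag: bool = False
    phenotype_note: str = ""

    def __post_init__(self):
        if self.category not in (1, 2, 3):
            raise ValueError("category must be 1, 2 or 3")
        if self.reroute_reason not in ("none", "unexpected_inheritance"):
            raise ValueError(f"bad reroute_reason {self.reroute_reason!r}")
        if self.reroute_reason == "unexpected_inheritance" and self.category != 2:
            raise ValueError("reroute implies category 2")
        if self.category == 3 and self.zygosity.zyg_class != "homozygous":
            raise ValueError("category 3 requires homozygous zygosity")

    @property
    def sample_id(self) -> str:
        return self.zygosity.sample_id

    @property
    def gene(self) -> str:
        return self.zygosity.gene


SEGREGATION = ("consistent", "inconsistent", "untestable")


@dataclass(frozen=True)
class KindredFinding:
    kindred_id: str
    gene: str
    shared_variant_keys: tuple
    zyg_class: str
    category: int
    tier: str = "none"
    segregation_status: str = "untestable"
    member_ids: tuple = ()

    def __post_init__(self):
        if self.segregation_status not in SEGREGATION:
            raise ValueError(f"bad segregation {self.segregation_status!r}")
        if self.category not in (1, 2, 3):
            raise ValueError("category must be 1, 2 or 3")


@dataclass(frozen=True)
class EnrichmentResult:
    variant_key: tuple
    cohort_ac: int
    cohort_an: int
    pop_ac: int
    pop_an: int
    p_raw: float
    p_adjusted: float = field(default=1.0)
    significant: bool = False
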