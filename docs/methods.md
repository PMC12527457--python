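# Methods

## Scope and data model

`tierpoi` starts downstream of alignment and variant calling: its inputs
are a multi-sample VCF (or pre-joined annotated calls), a per-allele
annotation table, an extended PED pedigree, and two gene-panel files.
Annotation is consumed, never computed — functional consequence,
population frequency (gnomAD v4-style allele fraction plus allele
counts), CADD/PolyPhen2/SIFT verdicts, ACMG class and splice predictions
are inputs. Positions are 1-based throughout (VCF convention); no
half-open conversion is ever applied. Multi-allelic records are
decomposed into one call per sample per alt allele; a genotype carrying
the alt allele twice is homozygous, once heterozygous. Genotypes of
ploidy other than 2 are treated as missing with a logged warning: the
target cohort is 46,XX, so no hemizygosity rule is required, and
X-chromosome heterozygotes behave exactly like autosomal heterozygotes.

## Filter cascade

Five independent predicates, evaluated in the order quality → in-silico
→ rarity → synonymous/splice → ACMG. All stages are always evaluated so
a rejected call can report every stage it failed; retention requires all
five. Operator conventions are deliberate and tested at their
boundaries:

| stage | rule | default | convention |
|---|---|---|---|
| quality | call quality and read depth | ≥ 20, ≥ 10 | inclusive |
| in-silico | damaging votes among CADD > cutoff, PolyPhen2, SIFT | 2 of 3, CADD cutoff 15 | CADD strict; missing verdicts are non-votes |
| rarity | population allele fraction by zygosity context | < 1e-4 biallelic, < 5e-5 monoallelic | strict; af = 0 or absent counts as novel and passes |
| synonymous/splice | synonymous and intronic changes excluded unless splice-affecting | 7-base intronic window | see below |
| ACMG | clinical class | P or LP only | missing class fails |

The *rarity context* of a variant depends on the zygosity of its gene in
that sample: homozygous and probable compound-heterozygous members are
biallelic, lone heterozygotes monoallelic. Because removing one member
of a compound-het pair demotes the survivor to the tighter monoallelic
threshold, the screen iterates zygosity resolution and the cascade to a
fixed point; the surviving set only shrinks, so this terminates and is
order-independent.

**Established-variant bypass.** A per-variant allowlist flag
(`established_pathogenic`) marks variants with a well-established
relationship to POI. Flagged variants skip the in-silico and rarity
stages but never quality, the synonymous/splice rule or the ACMG
requirement. The breadth of the bypass is a deliberate design choice:
several well-known published POI variants (the classic BMP15 p.L148P
among them) have population frequencies far above any of the rarity
thresholds, so a bypass confined to the in-silico stage could not retain
them. The table fixtures derive this flag programmatically: a printed
variant whose printed frequency reaches its context threshold carries
the flag, encoding the judgment the original screen evidently applied.

**Splice retention.** Synonymous and intronic changes are excluded
unless splice-affecting. A `splice_site` consequence is retained when a
splice-loss prediction is positive — this covers both canonical-site
variants and deeper intronic variants with a positive splice-model
(e.g. maximum-entropy) prediction. Plain `intronic` calls additionally
require the position to lie within 7 bases of the exon boundary; exonic
synonymous changes require a positive prediction. The splice predictor
itself is pluggable input, not computed here.

## Category routing

Decision order for one resolved gene zygosity (total and deterministic):

1. gene on panel 1 and zygosity model (biallelic for homozygous or
   probable compound het, monoallelic for a lone het) ∈ the gene's
   expected inheritance → **Category 1** with the panel tier
   (green/amber/red);
2. gene on panel 1, zygosity unexpected → **Category 2**, with
   `reroute_reason=unexpected_inheritance`;
3. gene on panel 2 → **Category 2**;
4. homozygous in an unlisted gene → **Category 3** (novel-candidate
   forward screen);
5. otherwise discard.

A gene on both panels is a configuration error at load. The cohort
screen makes three passes in this order; the Category 3 pass runs
cohort-wide, including individuals who already hold Category 1/2
findings. Category 3 findings in genes on a configurable
other-phenotype list (e.g. a gene established to cause retinal
dystrophy) are flagged and excluded from candidate counts but retained
in all reports.

## Inheritance labels

Each individual (or kindred) with ≥ 1 Category 1/2 finding receives
exactly one label:

1. all Category 1/2 findings homozygous → **AR** — co-occurring
   homozygous recessive findings (as seen in consanguineous kindreds)
   remain recessive rather than "oligogenic";
2. findings in ≥ 2 distinct genes → **oligogenic**;
3. single gene: homozygous → **AR**; probable compound het → **CH**;
   lone het → **AD**.

Rule 1's priority over rule 2 is the one place the labeling goes beyond
a naive gene count; it reproduces the published tables' treatment of an
individual carrying two independent homozygous findings. Two
heterozygous variants in one gene are only ever a *probable* compound
heterozygote; if parental genotypes prove the pair in cis it collapses
to the lower-frequency single heterozygote.

## Kindred aggregation and segregation

Familial findings are aggregated per gene by intersecting variant sets
across *recruited affected* members only; kindreds with a single
recruited member pass through with segregation untestable. Segregation
against unaffected relatives assumes full penetrance for dominant
findings (a carrier unaffected relative flags the finding inconsistent
but never drops it) and the usual recessive rules (an unaffected
homozygote, or carrier of both compound-het alleles, is inconsistent).

## Statistics

Two-tailed Fisher exact tests use the point-probability rule: sum all
hypergeometric point probabilities not exceeding that of the observed
table, with a relative tie guard of 1 + 1e-7 (the convention of
mainstream statistics libraries). The implementation evaluates the
hypergeometric pmf over the whole margin class (scipy's `hypergeom`),
which makes exhaustive verification cheap; the test suite checks it
against a `math.comb` enumeration oracle for every 2×2 table with total
n ≤ 60 (agreement < 1e-12) and against an independent library
implementation on random tables. Benjamini–Hochberg adjustment is the
standard step-up procedure (delegated to statsmodels), applied batch-wise
over all variants tested in one run; the family size is therefore "all
variants surviving to enrichment in the run" and is recorded in the run
log. Enrichment against the population reference builds allele-count
tables [[cohort_ac, cohort_an−ac], [pop_ac, pop_an−ac]] — allele counts,
not carrier counts, since allele frequency is the thresholded quantity —
with a 1.6-million-allele default denominator. Adjusted significance
cutoffs default to 1e-4 for per-variant enrichment and 0.05 for cohort
contrasts. Enrichment is computed and reported for every surviving
variant but does not gate retention by default (`require_enrichment`
flips this): with ~300 cohort alleles against 1.6 million, a variant
seen once in the cohort cannot approach adjusted p < 1e-4, and a hard
gate would empty the reported tables.

Cohort percentages are computed on exact counts and rounded half-up to
one decimal only at presentation. Sporadic summaries count individuals,
familial summaries count kindreds, and the merged summary counts
"entities" (sporadic individual = 1, familial kindred = 1); both
per-individual and per-entity tables are always emitted.

## Synthetic data

The generator emulates the study's cohort structure — 118 sporadic
probands and 17 familial kindreds (31 recruited affected members;
8 kindreds consanguineous) — with a per-entity composition over planted
finding classes whose defaults mirror the sporadic cohort's observed
proportions (about 7% homozygous Category 1, 12% heterozygous Category
1, 29% heterozygous Category 2, 22% oligogenic, 2% novel-candidate
homozygotes, the remainder finding-free). Planted variants satisfy every
filter by construction; allele frequencies are drawn below the
stratum-appropriate threshold (half exactly zero, i.e. novel), call
qualities 30–100, depths 20–150, CADD 16–40. Consanguineous kindreds
preferentially receive the homozygous plant classes. Decoy variants each
violate exactly one named stage and are recorded per stage in the truth
manifest, so tests can assert that every decoy is rejected at its
constructed stage and no plant is lost. The synthetic genome is a single
invented contig with invented coordinates; there is no linkage
disequilibrium, no haplotype structure, no read-level error model, and
population frequencies are independent draws rather than a site
frequency spectrum. Passing recovery tests therefore demonstrates the
correctness of the decision logic, not robustness to the noise of real
exomes.

The table fixtures are the complementary instrument: they encode the
published familial and sporadic variant tables literally (gene,
transcript, HGVS, zygosity, printed inheritance, printed population
frequency) and expand them to annotated calls with invented coordinates.
Running the pipeline over them reproduces every printed count. Two
printed inconsistencies in the source tables are preserved as-is and
surface in the outputs: the familial homozygous proportion (the tables
contain 5 AR-labeled kindreds, 29.4%, not 6) and the merged-entity
denominators (the tables yield 2 compound-het entities and 86 entities
total, so AD = 46/86 = 53.5% and AR = 10/86 = 11.6%).

## Problem sizes and determinism

Default test and reproduction runs use the full 149-proband fixture
cohort, simulated cohorts of the same size, and exhaustive Fisher
verification to n = 60 — all complete in well under a minute except the
exhaustive enumeration (~25 s). All randomness flows through a single
`numpy` generator seeded from the CLI/config; identical seed and config
produce byte-identical output files (hash-checked in the tests).

## Known limitations

* Phase is never inferred statistically; compound heterozygotes remain
  "probable" without parental genotypes.
* Dominant segregation checks assume full penetrance; incomplete
  penetrance would flag true findings inconsistent (they are retained
  and flagged, not dropped).
* The ACMG class and all in-silico scores are trusted inputs; no
  evidence-code engine is included.
* Biological triage of Category 3 candidates (animal-model support,
  expression evidence) is manual curation, outside the pipeline.
* No structural variants, no liftover, no hemizygous-X rule.
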