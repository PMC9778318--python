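# Methods

## Scope and data model

The package re-implements a trio transmission analysis for a hybrid
mother/father/offspring design (horse mare × jack donkey → mule).  Input is
a multi-sample VCF with GT/AD/DP per sample and the standard site QC
annotations (QD, FS, MQ, MQRankSum, ReadPosRankSum, HaplotypeScore), plus
BED3 mask tracks (repeats, CNVs, assembly gaps, indel anchors), GFF3 gene
models and a gene→pathway TSV.  Alignment and variant calling are upstream
of this package; the VCF is taken as given.

Internally every coordinate is 0-based half-open; conversion to the
1-based conventions of VCF and GFF3 happens only at the format boundary.
Half-missing genotypes (`./1`) are treated as missing: read-support
operations refuse to guess.  Only a configured chromosome set (the
autosomes, in the motivating design) is analysed; other records are
dropped with a logged count.

## Filter cascade

Hard filters use strict comparisons, exactly as in the GATK-style filter
expressions they mirror: QUAL < 30, QD < 2.0, FS > 20.0, MQ < 20.0,
MQRankSum < −3.0, ReadPosRankSum < −3.0, HaplotypeScore > 13.0, and the
SNP-cluster rule (any 3 consecutive SNPs spanning ≤ 9 bp, i.e. within a
10 bp window, flags all members — the GATK SnpCluster convention).  An
absent annotation never trips its filter: rank-sum statistics are undefined
at sites without reference reads, and discarding sites for missing metadata
would be over-aggressive.

Region filters: repeat/low-complexity and CNV mask membership (CNVs matter
because a heterozygous deletion is miscalled as a homozygous genotype and
shows up as a spurious MIE); exclusion within 50 bp of an indel anchor;
exclusion within 13 bp of an assembly-gap edge (the gap rule's source
phrasing — "within 3 bp and adjacent 10 bp" — is ambiguous; we adopt the
most conservative reading, 3 + 10 bp, both knobs configurable); and the
4 ≤ depth ≤ 50 window, inclusive on both ends.  The depth window has two
modes: `all` (every trio member in-window; the default for trio
classification, since an error in any member corrupts the transmission
call) and `offspring` (per-genome summary statistics use per-sample depth).

All filters are pure predicates; the verdict is their union and is
order-independent by construction.

## Inheritance classification

The genotype classifier enumerates the four possible
one-allele-from-each-parent transmissions.  De novo (any offspring allele
absent from the pooled parental alleles) takes precedence; a non-Mendelian,
non-de-novo site is an MIE whose origin is the unique parent whose
genotype contains every offspring allele.  An `UNDETERMINED` origin
category exists defensively but is provably unreachable under this rule —
any zero-owner or two-owner configuration is Mendelian or de novo instead —
and the test suite asserts determinacy exhaustively for up to three
alleles.

The read-count re-genotyper calls a sample's genotype directly from AD:
missing below 10× coverage; an allele is present iff its read fraction is
≥ 0.20 **and** a one-sided binomial tail P(X ≥ k | n, ε) ≤ 0.05 rejects
sequencing error alone (per-read error ε = 0.01 by default; this explicit,
testable error model stands in for the significance machinery of
read-based trio callers whose internal test is not part of the published
parameter set).  The genotype is the two highest-frequency present alleles;
frequency ties break toward the reference allele, then lexicographically,
for determinism.

A non-Mendelian state is reported only when both classifiers agree (the
intersection rule).  When the genotype classifier is non-Mendelian but the
read-based one disagrees, discordant samples are re-called once under
relaxed thresholds (frequency ≥ 0.05, p ≤ 0.15) — this rescues genuinely
present low-frequency parental alleles that would otherwise masquerade as
de novo events — and a disagreement that survives relaxation demotes the
site to Mendelian (if the re-call says so) or unclassified.

Retention rules for non-Mendelian calls: offspring genotype alleles
supported by ≥ 10 reads in total, ≥ 5 reads per allele for a heterozygote
(≥ 10 on the single allele for a homozygote), and ≥ 10× depth in each
parent.  The ≥10-read rule is applied to the offspring (the member carrying
the call); the per-parent depth floor covers the parents.  Calls failing
retention are kept in the output with `retained = False` and tallied as
unclassified so the tallies always partition the input.

## Statistics

Per-genome summaries count heterozygous and homozygous non-reference
genotypes and classify substitutions as transitions (A↔G, C↔T) or
transversions.  %SNP and %heterozygosity are taken against an explicit
`callable_sites` denominator — it is a required input, never inferred,
because the motivating study prints rates but not their denominator.  All
reported ratios and percentages round half-even to 2 decimals, computed on
the exact fraction via `decimal` to avoid float drift.

The de novo rate is count/callable_sites per *haploid* site per generation
(no factor of 2): that convention reproduces the published rate
(555 / 2.511 × 10⁹ ≈ 2.21 × 10⁻⁷) from its published count.  Cross-trio
comparisons use the floor of the quotient ("almost k times").

One printed inconsistency is documented rather than matched: the published
region-distribution lists 149 UTR5 SNPs as 0.58%, but 149/26,258 rounds to
0.57% at 2 decimals; the package computes 0.57.  Likewise the printed
per-region counts sum to 26,244 while percentages are taken against the
26,258 non-Mendelian SNPs, so `distribution_report` accepts an explicit
total.

## Region annotation

Precedence-based, as in ANNOVAR-style annotators: exonic > UTR5 > UTR3 >
intronic > ncRNA_exonic > ncRNA_intronic > upstream > downstream >
intergenic; when transcripts disagree the highest-precedence label wins.
Upstream/downstream means within 1,000 bp of the gene's strand-aware
5′/3′ end (the window is an annotator-convention default, configurable —
the motivating study states only the intergenic rule).  Intergenic sites
are assigned their nearest gene(s) only within 5,000 bp.  A coding-gene
exon position outside both CDS and annotated UTRs is labelled exonic.
Because a SNP can be assigned several genes and classes are gene *sets*,
per-class gene counts can exceed SNP counts.

## Enrichment

A hypergeometric upper-tail test per pathway, P(X ≥ k) for
X ~ HG(N, K, n), with Benjamini–Hochberg adjustment across all tested
pathways (no procedure was named in the source analysis; BH is the field
default).  The universe defaults to all genes of the supplied annotation
and can be restricted to the pathway map's genes.  No significance cut-off
is hard-coded.

## Synthetic trio generator

The generator emulates the study conditions, not real genomes.  Defaults:

| parameter | default | basis |
|---|---|---|
| mother (horse) SNP rate | 0.0020 /site | published %SNP ≈ 0.20% |
| father (donkey) SNP rate | 0.0095 /site | published %SNP ≈ 0.95% |
| mother het fraction | 0.67 | 3,387,403/5,012,403 ≈ 0.676 |
| father het fraction | 0.08 | 1,996,879/23,819,055 ≈ 0.084 |
| mean depth | 30× (Poisson) | study sequenced ~38–46× |
| per-read error | 0.01 | Illumina-scale |
| MIE injection rate | 1 × 10⁻⁵ /site | 25,703 / ~2.5 × 10⁹ callable |
| de novo injection rate | 2.21 × 10⁻⁷ /site | published rate |
| QC-violation fraction | 0.02 of emitted sites | exercises each hard filter |

Sites are simulated independently (the analysis is site-wise; no LD), on a
regular grid far beyond cluster-window distance, with SNP-cluster test
cases planted explicitly as triples within 7 bp.  The offspring draws one
allele uniformly from each parent; an MIE site makes the offspring
homozygous for an allele carried by exactly one parent (the other parent
hom-ref) — the only by-construction violation geometry at biallelic
sites; a de novo site substitutes one transmitted allele with a base
absent from both parental genotypes (yielding a third allele when the
parents are variant).  Allele depths draw each read from the allele dosage,
then misdirect it with probability ε uniformly to the other three bases;
error reads landing outside the site's allele list are dropped from AD
(so ΣAD ≤ DP, as with real mapped-read accounting).  Masks are random
merged interval tracks (repeats 5% of the genome, CNVs 2%, gaps 0.5%,
indel anchors 5 × 10⁻⁵/bp); gene models are non-overlapping 2–10 kb genes
with 2–4 exons, strand-aware UTRs and CDS, ~20% noncoding.

What the generator does **not** model — linkage, alignment artifacts,
mapping bias between the diverged parental genomes, indel realignment
effects, genotyping-error modes other than symmetric read error — bounds
what passing tests show: they validate the *logic* of the cascade and the
classifiers under the stated noise model, not robustness to real-data
artifact structure.

`expected_counts` gives first-order analytic expectations (event-overlap
terms of order rate² are ignored; negligible against binomial noise at the
default rates).

## Problem sizes and numerical choices

The end-to-end recovery check runs 10⁶ scanned sites at 30× with planted
MIE 10⁻⁴ and de novo 2 × 10⁻⁵ (≈100 and ≈20 events), a scale at which the
binomial noise on recovery fractions is small while the whole suite stays
interactive; module-level tests use 2 × 10⁴–2 × 10⁵ sites.  De novo rate
recovery is judged by an exact Clopper–Pearson 95% interval.  Determinism:
a single seeded numpy Generator drives the simulator; fixed seed gives
byte-identical output files, and the pipeline's `summary.json` is
byte-identical across reruns (timestamps live only in the manifest).

## Known limitations

* No phasing or haplotype-block inheritance-state smoothing; sites are
  classified independently.
* Sex chromosomes are out of scope; the chromosome set is config-supplied.
* Multiallelic sites are classified on the full allele set without
  decomposition.
* The enrichment layer tests a user-supplied pathway map; it does not
  retrieve pathway databases.
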