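# Methods

## Scope and model of the analysis

The package formalizes a clinical prioritization workflow: a trio exome yields
candidate de novo loss-of-function variants, and RNA-seq from blood supplies
three independent lines of functional evidence — altered splice-junction usage,
novel (catalog-absent) junctions, and depletion of the alternate allele in
mRNA consistent with nonsense-mediated decay (NMD). Each stage is a pure
function of explicit inputs; the pipeline only composes them, so any stage can
be run alone on real files (VCF/SAM/BED/TSV).

## Filtering cascade

Rules fire in a fixed order and the first matching rule is recorded, making
decisions deterministic and auditable. Choices where the source procedure is
under-specified:

* Thresholds are applied as *removal when AF ≥ threshold*; the borderline band
  of rule ii is the closed interval [0.01, 0.05].
* Genes annotated both dominant and recessive use the stricter dominant
  frequency threshold; unknown inheritance does too (conservative removal of
  common variants, with de novo status checked before any inheritance rule can
  discard a variant).
* De novo calling needs parental depth ≥ 10 with ≤ 1 alternate read (defaults,
  configurable). Parents below that depth make the call "unresolvable", which
  is never treated as de novo.
* Compound heterozygotes require two proband heterozygotes with provably
  opposite parental origin; when phase cannot be resolved (a parent carries
  both variants), the variants are retained with a `phase_unknown` warning
  rather than silently dropped.
* Missing population frequency is treated as 0 (absent from the population
  database). Multi-allelic records are split into biallelic variants on read.

## Coordinates and consequence naming

Internal coordinates are 0-based half-open; VCF input and HGVS output are
1-based. Conversions live in `TranscriptModel` only. Deletion normalization
shifts maximally left in genomic space (VCF) or maximally 3' along the
transcript (HGVS); both representations of an equivalent deletion produce the
identical mutated sequence, and classification happens after the 3' shift so a
homopolymer deletion spanning an exon/intron boundary is always assigned to the
+1 donor position. Frameshift naming uses one-letter amino acids by default
("L524Tfs*3" style) with a three-letter option ("Asp20Ilefs*51" style); when
the first altered residue is itself a stop the call is nonsense (`p.X<n>*`),
since `fs*N` requires N ≥ 2; a shifted frame that never reaches a stop is
tagged `fs_no_stop`. Translation uses the standard code (table 1), no
selenocysteine handling.

## Junction statistics

Only primary, mapped, non-duplicate alignments are counted; each CIGAR `N`
operation contributes one junction observation, so counting is invariant to
read order and file sharding. Usage percentages are reported to one decimal
using largest-remainder allocation, which guarantees they sum to exactly 100.0
at any number of acceptors (plain rounding can drift by up to 0.05 per
acceptor). Novel-junction matching against the catalog is exact by default
(`slop` is available but off, because catalog comparison is categorical
absence); a flagged junction reports its usage fraction among junctions sharing
its donor and, separately, its acceptor — a novel-donor junction is otherwise
trivially 100% "of its own donor".

## Zygosity and allelic imbalance

The informal inspection "VAF ≈ 50% means heterozygous, clearly below means
mosaic" is formalized as an exact two-sided binomial test against p = 0.5
(depth ≥ 20 required; α = 0.05; mosaic band VAF in [0.05, 0.35]; VAF at/past
the 0.05 limit of detection is homozygous). NMD evidence is a one-sided Fisher
exact test on the 2×2 DNA/RNA allele-count table, alternative: RNA alternate
fraction lower. A table with a zero margin returns p = 1 with a "degenerate
table" note instead of failing. Percentages round half-up to one decimal.

## Splice-site models

Window conventions are the MaxEntScan standard (donor 9 = 3 exonic + 6
intronic; acceptor 23 = 20 intronic + 3 exonic). WMM and MM1 are trained by
additive smoothing (pseudocount 0.25 per base by default); scores are log2
odds against a uniform background (overridable), so background-equal models
score 0 and WMM scores are additive by position. The full maximum-entropy
model is *not* refit — its published parameters can be supplied as a k-mer
table (`MAXENT_TABLE`), and the maximum-dependence-decomposition family is out
of scope. The interpretive rule for variants is conjunctive: "splice-weakening"
only when delta < 0 under every available model family.

## Synthetic data: what it emulates, and what a green test establishes

The generator's defaults are the observed regimes the analysis is built
around: DNA depth 44 and RNA depth 138 at the variant site, mosaic fraction
0.30, parental acceptor usage (0.45, 0.55) with the proband shifted to
(0.38, 0.62), a proband-only aberrant junction at 13% usage, and an NMD factor
of 0.5 (the alternate-allele RNA reads are binomially thinned:
p_rna = p·nmd / (1 − p + p·nmd)). Background variants are common
(AF ~ U(0.05, 0.5)) with Mendelian-consistent genotypes drawn parent-first, so
the frequency rule removes them all and the planted de novo is the intended
sole survivor — the regime the cascade exists for. Splice-model training
windows are sampled from consensus-like positional frequencies with invariant
GT/AG cores.

Deliberately not modeled: sequencing error, mapping bias, GC/fragment-length
effects, UMI structure, genotyping noise in the parental genomes, and real
splice-site diversity. A green suite therefore establishes correctness of the
statistics and bookkeeping under the stated sampling model, not robustness to
real-data artifacts.

One RNG stream per simulation product, all derived from the single config
seed; identical seeds give byte-identical output files.

## Pipeline report

Candidates are ranked by the tuple (de novo, LoF consequence, number of
supporting RNA evidence sources) — a transparent stand-in for expert
prioritization, which in practice also uses phenotype matching. The report
echoes every threshold used, and ACMG-style tags (PVS1-like, PS2-like,
PM2-like) are informational labels derived from evidence already in the
report, never scored criteria. With no RNA input the report is still emitted
with RNA fields marked "not assessed".

## Numerical choices

* Exact tests come from scipy (`binomtest`, `fisher_exact`); the test suite
  checks both against independent enumeration oracles (exact rational
  hypergeometric/binomial tail sums) to 1e-10.
* Rounding of reported percentages is half-up (decimal arithmetic), matching
  the clinical reporting style; usage ratios use largest-remainder allocation.
* Ties in the largest-remainder allocation break by acceptor coordinate;
  intronic positions equidistant from two exons classify to the donor side.

## Known limitations

Single-transcript consequence calling (no multi-isoform aggregation); only
substitutions and pure deletions in splice classification; no haplotype
phasing beyond parental-origin logic; junction extraction assumes the aligner
already decided splice placement; MM1/WMM scores are not numerically
comparable to published MaxEntScan values (only signs/orderings are
interpreted).
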