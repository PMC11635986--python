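# Methods

This note records the statistical model, the conventions the implementation
fixes where the published descriptions leave latitude, the design of the
synthetic-data generator, and the limitations of what the test suite can
show about real data.

## Colocalization model

For one locus, one GWAS and one eQTL study, the engine evaluates the
standard five-hypothesis approximate-Bayes-factor model. Per variant and
study, the Wakefield log ABF is computed from the effect estimate and its
standard error,

    z = β̂/se, V = se², r = W/(W+V), lABF = ½[ln(1−r) + z²·r],

never from p-values when a standard error is available (a p+MAF+N fallback,
`log_abf_from_p`, reconstructs |z| from the two-sided normal tail and
approximates se = 1/√(2·n·f·(1−f)) for records lacking se). Hypothesis
likelihoods are

    L1 = LSE_i(lABF1ᵢ) + ln p1        L2 = LSE_i(lABF2ᵢ) + ln p2
    L4 = LSE_i(lABF1ᵢ + lABF2ᵢ) + ln p12
    L3 = ln p1 + ln p2 + ln(Σᵢ BF1ᵢ · Σⱼ BF2ⱼ − Σᵢ BF1ᵢBF2ᵢ)

with every sum in log space. The H3 log-difference is computed as
`lse12 + log(expm1(d))` with `d = lse1 + lse2 − lse12` and clamped to −∞ when
`d ≤ 1e-13`; this makes PP.H3 exactly zero for single-variant loci, where
the difference is identically zero and any nonzero value would be float
noise. Posteriors are the softmax of (0, L1..L4); `SNP.PP.H4` is the softmax
of `lABF1 + lABF2`. The test suite checks the implementation against an
independent arbitrary-precision (60-digit decimal) direct enumeration that
works in plain BF space, including the explicit O(Q²) H3 double sum.

**Priors.** p1 = p2 = 1e-4, p12 = 1e-5, the published defaults of the ABF
colocalization method; the source analysis does not restate them. Prior
effect sd is 0.15 for quantitative traits and 0.2 for case-control traits on
the log-odds scale, selected per study from its `trait_type` metadata. All
are configurable per run.

**Retention.** PP.H4 ≥ 0.75 at the locus level, then every variant with
SNP.PP.H4 ≥ 0.5 becomes one retained pair; both cutoffs inclusive.

## Harmonization conventions

* **Clumping** is greedy best-p-first (PLINK style): candidates below
  p = 5×10⁻⁸ in ascending p order, kept iff r² < 0.1 with every kept lead
  within 1 Mb. Ties in p break on (chrom, pos, variant id), making the
  output invariant to input order. The algorithm itself is not specified in
  the source analysis, only its parameters.
* **Window** radius is boundary-inclusive (|pos − lead| ≤ 1 Mb). The coloc
  candidate set is the variants present in both studies; restricting to
  genome-wide-significant variants in each study (the literal reading of the
  extraction step) is available via `significant_only=True`, but the default
  follows standard ABF-coloc practice of using all shared variants.
* **QC order**: frequency fill-in from the reference panel → strict
  frequency filter (0 < eaf < 1; missing-after-fill removed) → missing-stat
  filter → duplicate removal → MHC mask. Duplicated variant ids drop **all**
  copies (allele alignment of duplicates is ambiguous; keeping an arbitrary
  copy risks a sign error). MHC bounds chr6:25,000,000–35,000,000 are
  inclusive on both ends. QC is idempotent.

## Coordinates

Internal coordinates are 1-based inclusive everywhere; interval length is
end − start + 1. This convention is fixed by the published region table,
whose printed lengths equal end − start + 1 for every row (verified in the
regression fixture). BED (0-based half-open) and BEDPE conversion happens
only at the I/O boundary and is an exact inverse, property-tested over
random intervals. Chromosome labels normalize to `chrN` on input.

## Pleiotropy annotation and regions

A variant's categories/genes/tissues are set unions over its retained pairs;
a pleiotropic eQTL has ≥ 2 categories. Region building sorts qualifying
variants by (chrom, pos) and merges while the gap between *successive
variants* is strictly < 100,000 bp — the transitive closure of the pairwise
rule, which coincides with a 100 kb sliding window. Each qualifying variant
belongs to exactly one region (checked against a union-find oracle).

The region's gene marker is the most frequent gene among member pairs, ties
broken lexicographically. The published analysis ranks genes by PubMed
citation count, which needs an external service; frequency is this package's
documented proxy.

Explained-loci proportions use the Wilson score interval at 95% (the source
states only the confidence level); a lead is explained iff a retained pair
of the same GWAS lies within 1 Mb (inclusive, mirroring the window rule).
Per-category values average the per-study proportions.

## Enrichment

All enrichments are 2×2 odds ratios of an annotation flag in a
category-count bin ({1, 2, ≥3}; configurable) against the single-category
baseline. Zero cells get the Haldane–Anscombe +0.5 correction for the OR
point estimate only; Fisher exact p-values are always computed on raw
counts (scipy), and the suite verifies them against a direct hypergeometric
enumeration. Sidedness defaults: one-sided (greater) for annotation-track
enrichment, two-sided for consequence-class comparisons, following the
respective figure conventions of the source analysis.

The transcription-factor window around a variant is the closed interval
[pos − 10, pos + 10]: the "radius 10 bp / window 20 bp" phrasing is
internally inconsistent by 1 bp and the radius wins. Loop containment uses
the outer span (anchor A start to anchor B end); an inner-span mode is
available. Gene distance is 0 inside the gene body, else distance to the
nearer gene edge; a TSS-based mode exists because "distance to gene" is not
otherwise pinned down.

## Trait similarity

Each trait's effect vector maps (variant, gene, tissue) keys to eQTL betas;
duplicate keys keep the entry with the highest SNP.PP.H4. Pairs of traits
sharing ≥ `min_overlap` keys (default 10; the source states only "a minimal
number" without a value — reported in output metadata) get a Spearman rho.
The trait filter keeps traits with |rho| ≥ 0.05 against ≥ 30 other traits,
both bounds inclusive, applied once (an iterative fixed-point variant is
behind a flag; whether the original filter was re-applied after removals is
unstated). Clustering is average-linkage agglomeration on d = 1 − rho with
missing correlations imputed as d = 1; anticorrelated traits are therefore
maximally distant, a deliberate choice the alternative d = 1 − |rho| would
reverse. Leaf order and tie-breaks are deterministic; the merge tree is
exported as Newick.

## Synthetic-data generator

Summary statistics are simulated directly in z-space: for a locus of Q
variants with AR(1) LD matrix R (r(i,j) = ρ^|i−j|, default ρ = 0.9),
z ~ MVN(R·λ, R) where λ carries the causal noncentrality (default 8
z-units). Allele frequencies are uniform on [0.05, 0.95];
se = 1/√(2·n·f·(1−f)), β̂ = z·se, p the two-sided normal tail. No
individual-level genotypes exist: this is the minimal sufficient model for
an engine that consumes (β̂, se), and it keeps full-cohort generation under a
second. Scenario labels (null / gwas_only / eqtl_only / distinct / shared)
fix the causal configuration; `distinct` places the two causal variants at
opposite locus ends, where AR(1) correlation is negligible (r² < 0.01 for
Q ≥ 50 at ρ = 0.9).

The default cohort plants one shared-causal locus per entry of
`planted_category_counts = (1, 1, 1, 2, 2, 3, 4)` — GWAS traits from that
many distinct categories plus two genes × two tissues of eQTL studies per
locus — with default sample sizes n = 50,000 (GWAS, case-control scale) and
n = 5,000 (eQTL), plus distinct and null loci as negatives, 10% masked
allele frequencies (refillable from the emitted reference panel), an
enhancer track planted at odds ratio 2.5 over the pleiotropic causal
variants, loops around each shared locus, and a consequence table. All
randomness flows from the single config seed; identical seeds give
byte-identical directory trees. `plant_enrichment` chooses coverage
probabilities so the *expected* 2×2 odds ratio equals the target:
odds(flagged) = OR × odds(base coverage 0.3).

What the generator does **not** emulate: realistic MAF spectra, reference
LD panels with long-range structure, sample overlap between studies,
winner's-curse effect-size inflation, or genome-wide scale. Passing
recovery tests therefore demonstrates the correctness of the machinery
under the stated model, not the field performance of ABF colocalization on
real corpora, whose headline counts depend on hundreds of external studies.

## Problem sizes

Recovery simulations use Q = 200 variants, n = 50,000, noncentrality 8,
ρ = 0.9 with 200 shared, 200 distinct and 500 null loci — large enough for
stable medians and a meaningful false-positive bound (< 1%), small enough
that the whole suite runs in seconds. Oracle sweeps use 100 random clumping
instances (≤ 15 variants), 200-variant merge partitions, and 400 sampled
2×2 tables with total ≤ 50 for the exact-test comparison.

## Known limitations

* Multi-allelic variants are keyed by variant id only; duplicate ids are
  removed wholesale at QC rather than resolved by allele.
* LD is consumed as given (block matrices); r² is never computed from
  genotypes, and variants missing from the LD matrix are an error at
  clumping, not silently independent.
* Cytoband labels and PubMed-based gene ranking are out of scope (the
  region table accepts a cytoband column as pass-through only).
* The explained-loci per-category averaging treats each GWAS equally
  regardless of its lead count; a pooled mode is the natural alternative
  and both are exposed.
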