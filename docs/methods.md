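# Methods

## Scope and model

`lncpair` analyzes the joint response of protein-coding genes (PCGs) and
long noncoding RNAs (lncRNAs) in a multi-group expression design: six
sample groups (two enterotypes × three treatments), four treated-vs-vehicle
comparisons within enterotype, FPKM expression units, and a gene-level
annotation for both feature classes. The quantity of interest is the set of
*cis* lncRNA–PCG pairs: lncRNAs positioned in or immediately around a
coding gene whose expression changes together with it.

## Coordinates and gene models

Internal coordinates are 0-based half-open; GTF I/O (1-based fully closed)
converts at the boundary. This makes interval arithmetic (unions, introns,
distances) unambiguous. Multi-transcript genes collapse to one gene-level
model: exons are unioned across transcripts and CDS bounds are the
outermost CDS coordinates, matching the gene-level resolution of the
expression matrices (one FPKM per gene id). Genes on unplaced contigs are
retained; lncRNAs on chromosomes without coding genes are intergenic.
Transcript-level isoform structure is out of scope.

The interval index answers overlap queries through an interval tree and
nearest-gene queries through sorted span-endpoint arrays; by construction
its answers equal a linear scan, and the tests enforce that equivalence
against a brute-force oracle.

## Presence filter

A feature is expressed when its arithmetic mean FPKM reaches 1.0 in at
least one group. The boundary value 1.0 counts as expressed — the filter is
defined as the complement of "below 1 in every group". The threshold is a
config key (`min_fpkm`); 1 FPKM is the conventional detection floor for
liver RNA-seq.

## Differential expression

The built-in test is Welch's two-sample t on log2(FPKM + 1), applied per
feature per comparison to the presence-filtered set. This is a deliberate,
documented stand-in for whatever count-model tool produced a user's own
tables: the `import_de_table` path accepts external results (feature,
comparison, log2fc, p) and recomputes significance under the configured
threshold, so fidelity to any specific caller is preserved where it
matters. Design choices:

* significance is strict raw p < 0.05 by default; Benjamini–Hochberg
  adjustment (within comparison) is available via `adjust="BH"`. Both
  conventions appear in published analyses of this design, so both are
  exposed and neither is silently preferred;
* log2 fold-change is log2((treated + ε)/(control + ε)) with ε = 0.001 —
  small enough to preserve the several-hundred-fold inductions this kind of
  exposure produces, while keeping total-abolition cases finite (reported
  as "100% decrease");
* the +1 pseudocount inside the log transform stabilizes variance at low
  expression for the test statistic;
* features with zero variance in both groups get p = 1 and are never
  significant;
* groups of n = 2 are accepted (the emulated design contains one), n = 1 is
  rejected;
* comparisons are tested independently — no pooling of multiple-testing
  across the four contrasts.

Under the null (no planted effects, 10,000 features, n = 3 vs 3, log-normal
noise) the raw-p rejection rate at α = 0.05 measures within [0.03, 0.07]
(see `scripts/acceptance.py`); the mild conservatism comes from the
pseudocount's variance compression at low expression.

## Genomic categorization

Each lncRNA receives exactly one of seven categories relative to its
closest PCG — upstream (≤ 5 kb of the TSS), 5′-UTR, exon, intron, 3′-UTR,
downstream (≤ 1 kb of the TTS), or intergenic. Decisions that were
genuinely open:

* **Anchor rule.** Categorization keys on the lncRNA's strand-aware 5′ end,
  not on maximal overlap: a locus transcribed from an intron that runs into
  the 3′-UTR is filed as intronic, by its origin. A spanning query has no
  published priority order, so the anchor rule is adopted as a transparent,
  deterministic convention.
* **Gene strand frame.** Upstream/downstream and UTR sidedness are defined
  by the *gene's* strand; the lncRNA's own strand never changes the
  category (an antisense overlap classifies by position).
* **Inclusive windows.** "Up to 5 kb / 1 kb" is read as ≤: an anchor at
  exactly 5,000 bp upstream is upstream, at 5,001 bp intergenic.
* **Closest gene.** Distance is measured anchor-to-span (0 inside), and
  ties break to the lexicographically smallest gene id. A locus whose
  anchor is outside all windows but whose body overlaps a gene stays
  intergenic by category; the overlap is recorded on the annotation record
  because pair identification uses it.

## Pair identification

A pair (L, G) for a comparison requires: G is L's closest PCG; L overlaps
G's span (any ≥ 1 bp body overlap, strand-independent) or L's anchor lies
within the windows (equivalently, L's category is non-intergenic); and both
L and G are significant in that comparison. Restricting to the closest gene
means one lncRNA yields at most one pair per comparison, while one gene may
partner several lncRNAs. Concordance (same/opposite direction) is reported
but is not a criterion — both co-regulated and oppositely regulated pairs
are biologically meaningful. The per-comparison counting chain (DE lncRNAs
→ non-intergenic subset → paired subset) is monotone non-increasing by
construction.

## Venn partition and patterns

Venn membership is binary significance per comparison. Pattern vectors are
defined only for features significant in all four comparisons: the ordered
signs of log2fc over (CV_BDE-47, CV_BDE-99, GF_BDE-47, GF_BDE-99), with
named aliases for the four recurring profiles (all-up; all-down; down
everywhere except up under BDE-99 without microbiome; up with microbiome,
down without). A significant call with log2fc = 0 is unconstructible by the
result-type invariant, so sign vectors are always well defined.

## Synthetic data generator

The generator emulates the features of the real design that the pipeline's
correctness depends on, with defaults chosen once:

* **Groups.** Six groups sized (3, 4, 2, 3, 3, 3) — deliberately unbalanced
  to exercise the n = 2 code path in the test statistic.
* **Genome.** Non-overlapping multi-exon genes (3–6 exons, 150–400 bp
  exons, 0.5–3 kb introns, CDS inset ≥ 60 bp from both transcript ends so
  both UTRs exist), separated by 20–40 kb gaps. The gaps dominate the
  5 kb/1 kb windows, so each lncRNA's intended host is provably its
  closest gene.
* **lncRNA placement.** Quota (exact-count, largest-remainder) placement
  over the seven categories, so distribution tests are exact rather than
  multinomial. Default proportions 44/26/16/5/4/4/1% for intron/
  intergenic/3′-UTR/downstream/upstream/exon/5′-UTR — the profile typical
  of differentially regulated liver lncRNAs. Every placement is verified
  by re-annotation before emission.
* **Expression.** FPKM = baseline × 2^effect × 2^N(0, σ) with log-normal
  baselines (log2 mean 3.5, sd 1.5, floor 1.0 for expressed features), a
  non-expressed stratum drawn below 0.1 FPKM (default fraction 0.55), noise
  σ = 0.25 on the log2 scale, and planted effects of magnitude ~2 log2
  units. Planted pairs are intronic lncRNAs in distinct host genes, forced
  into the expressed stratum, with a configurable same/opposite
  concordance mix (default 0.8 same).
* **Decoy hygiene.** Background DE features are selected so they cannot
  form pairs by construction (DE lncRNAs avoid pair-gene neighborhoods; DE
  genes are never the closest gene of a DE lncRNA). The planted pair list
  is therefore the complete ground-truth pair set, which makes
  recall/precision well defined. Residual false positives can still arise
  from type-I errors meeting by chance; at α = 0.05 this costs a few
  percent of precision, which the acceptance measurement reflects.

What the generator does *not* emulate: read-level sampling noise, FPKM
estimation uncertainty, transcript isoforms, overlapping genes,
correlated (batch) noise, and heavy-tailed outlier samples. Passing tests
therefore demonstrate the correctness of the analysis logic under the
stated generative model, not robustness to every artifact of real RNA-seq.

## Problem sizes

Default simulations use 80 genes and 300 lncRNAs per run; the annotation
oracle checks use 48 genes × 520 loci; pair recovery averages 20 seeds; the
null calibration uses 10,000 features. These sizes give stable estimates
(binomial sampling error on a rate at n = 10,000 is ±0.4%) while keeping a
full suite run in seconds.

## Known limitations

* The built-in Welch test is not a count model; with n = 2 per group its
  degrees of freedom can collapse to ~1, which costs power in the smallest
  group's comparison — visible as recall slightly below 1 in the recovery
  measurements. Import externally computed tables when a count model is
  required.
* Annotation against transcript-level models (rather than gene-level exon
  unions) is not supported.
* The Venn partition is exact set algebra; no proportional-area rendering
  is provided.
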