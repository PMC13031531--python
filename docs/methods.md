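# Methods

## Data model and conventions

All intervals are 0-based half-open internally; VCF (1-based) and BED
(half-open) convert at the I/O boundary only. Four SV classes are
supported — DEL, INS, DUP, INV — and breakends/complex events are skipped
at read time with a logged count. Insertions are anchored at a single
breakpoint (`end = start + 1`) with the inserted length carried
separately, because caller dialects disagree on what END means for an
insertion. For symbolic records, the POS base is treated as the first
affected base (`start = POS − 1`); when both END and SVLEN appear, SVLEN
defines the span from that start, since htslib re-derives END from SVLEN
under the padding-base convention and the two cannot both be honoured.
Consensus VCFs therefore carry END (not SVLEN) for spanning types and
SVLEN only for insertions.

Every variant is treated as biallelic: allele indices above 1 collapse to
a single non-reference class. This mirrors how the SV catalog itself is
built — allele-resolved SV boundaries cannot be called reliably, so all
non-reference alleles at a site form one class — and is applied uniformly
to SNPs for consistency. The cost is that LD against a truly multiallelic
site can be overestimated; D′ is the more robust of the two statistics in
that regime, which is why thresholds on the catalog side are phrased in
D′. Contigs outside chr1–22, X, Y are dropped.

## Consensus merge

Matching is type-specific. DEL/DUP/INV match when their reciprocal
overlap — `min(|a∩b|/|a|, |a∩b|/|b|)` — is at least 0.5; insertions match
when breakpoints are within 1,000 bp (inclusive) and the length ratio
`min/max` is at least 0.5. Merging proceeds in three steps per sample:

1. **Within PacBio CLR**: pbsv calls are first deduplicated — same-type
   calls that mutually match *and* overlap the same repeat element
   collapse to the longest (ties: leftmost). The type-specific match
   predicate stands in for "similar breakpoints", which has no separate
   distance definition. pbsv calls then seed clusters and Sniffles calls
   tag them.
2. **Within linked reads**: Manta anchors; CNVnator, ERDS and Long Ranger
   attach in that order. Long Ranger contributes deletions only.
3. **Across platforms**: platform-level clusters are matched; pairs emit
   one call with the PacBio boundaries and genotype.

A supporting call attaches to the best-matching existing cluster — highest
reciprocal overlap for spanning types, smallest breakpoint distance then
closest size ratio for insertions, remaining ties to the leftmost
representative — or seeds a new cluster, so unique calls are always
retained. Tagging is one-to-one: each supporting call joins at most one
cluster and each cluster takes at most one call per supporting caller,
which prevents a caller's split calls from collapsing a cluster's
boundaries. Cluster representatives are the arithmetic mean of member
starts and ends, rounded half-up; insertion lengths average the member
lengths. Cluster genotype is the anchor member's genotype.

Cross-sample consolidation is greedy single-linkage in (chrom, start)
order against the running mean representative. Clusters whose members are
all ≤ 50 bp are dropped (strict >50 bp floor), and SVs carried by fewer
than three participants are removed (a sample with any non-reference
genotype counts as a carrier, heterozygous or homozygous). Samples absent
from a cluster are homozygous reference; when only one platform called a
matched SV in some sample, that sample keeps its platform-of-origin
genotype. NAF is the fraction of non-missing haplotypes carrying the
non-reference class. On fixtures whose match graph is a disjoint union of
cliques, greedy consolidation provably equals the connected-component
partition, and the test suite checks this equivalence against a
brute-force all-pairs oracle; on non-clique graphs (chained overlaps)
greedy output is order-dependent by construction, which the canonical
pre-sort makes deterministic.

## LD engine

LD is computed by direct counting on phased haplotypes — no EM estimator
is provided, because the pipeline requires phased input downstream of
statistical phasing. Haplotypes missing at either locus are excluded
pairwise; the retained count is reported per pair. A monomorphic locus on
the retained haplotypes makes the pair *undefined* (dropped with a logged
count), never zero. D′ is reported as a magnitude in [0, 1] with the sign
of D carried separately, so that "D′ ≥ 0.8"-style thresholds read
naturally; both D′ and r² are invariant under allele relabeling, so the
orientation (SV non-reference vs SNP alternate) is purely a reporting
convention.

Pairs are formed for GWAS SNPs within 1 Mb of the SV, measured to the
nearest SV edge (to the breakpoint for insertions), boundary inclusive.
SVs are filtered to MAF ≥ 0.1 (`min(NAF, 1−NAF)`); SNPs are filtered by
GWAS Catalog p-value < 1e-6, not by frequency.

## Catalog join

LD results join GWAS Catalog associations on (chromosome, position,
reference allele, alternate allele). Strict mode requires allele
identity; a lenient mode (position + rsid) exists because catalog rows
frequently omit a usable risk allele. No strand-flip or ref/alt-swap
rescue is attempted. A SNP with k trait associations yields k entries.
−log10(p) is capped at 300 to survive underflowed catalog p-values.
Stratified counts use the six-context vocabulary with gene-proximal
precedence (exon > 5′UTR > 3′UTR > intron; intergenic otherwise); the
"all" stratum ignores the D′ threshold, and counts are monotone
non-increasing in the threshold by construction.

## Benchmarking

Reference-set matching re-implements the Truvari bench predicate rather
than shelling out: same type, minimum of start- and end-breakpoint
distances ≤ `refdist` (500 bp default — an approximation of Truvari's
reference-context semantics, stated as such), length ratio ≥ `pctsize`
(0.7), and reciprocal overlap ≥ `pctovl` (0.5) for non-insertions.
Sequence similarity is not compared because consensus calls carry no ALT
sequences. Matching is greedy one-to-one in sorted order, taking the
closest unmatched candidate; recall = matches/n_base, precision =
matches/n_comp. NAF-stratified recall uses strict `NAF > t` strata and
flags an empty stratum as undefined (NaN). Genotype concordance compares
unphased genotype classes over matched pairs, excluding pairs with a
missing genotype from the denominator.

Agreement of paired NAF values is summarized with Lin's concordance
correlation coefficient, `ccc = 2s_xy / (s_x² + s_y² + (x̄−ȳ)²)` with 1/n
moment estimators per Lin's original definition. The 95% CI uses the
Fisher z-transform with Lin's (1989) standard error (the form standard in
epidemiology packages); degenerate cases (|ccc| = 1, zero correlation)
return a point interval, and zero total variance is an error.

## Annotation

Feature overlap is ≥ 1 bp against interval-indexed tracks. A TAD boundary
is flagged only when the SV extends strictly on both sides of a block
edge. Gene models are consumed as BED-like intervals with exon/UTR
substructure, one transcript per gene (MANE-style). Gene relations rank
full-gene encompassment over exon–intron-junction crossing over
gene-boundary overlap over containment. The covariate table delivers one
row per SV — NAF, type, length, GWAS SNPs within the LD window, max D′
and r², and one indicator per feature class — so any GLM tool can fit the
feature-overlap association models; the regression itself is a routine
fit and out of scope here.

## Synthetic generator

The generator's defaults emulate the study conditions the pipeline
targets: 101 samples, SV lengths from a two-mode lognormal mixture at
300 bp and 6,000 bp (the Alu and LINE peaks, weights 0.7/0.3, σ = 0.35,
floor 60 bp), a type mix dominated by insertions and deletions
(0.45/0.45/0.06/0.04), and per-SV NAF drawn uniformly on [0.02, 0.7] with
Hardy–Weinberg genotypes. Truth SVs are spaced at least 5 kb apart so
consensus clusters are unambiguous at these noise levels. Caller noise
profiles (detection probability, Gaussian breakpoint jitter, fractional
length jitter, Poisson false positives, genotype flips) are simple
independent-noise models chosen to reflect relative caller strengths —
long-read callers sensitive with tight breakpoints, read-depth callers
restricted to copy-number classes with coarse boundaries, Long Ranger
deletions only. They make no attempt to mimic real callers' correlated
error structure, so passing merge tests demonstrates the merge logic, not
performance on real data.

Haplotype columns at target LD are constructed from counts, not sampled:
cell probabilities `(p_AB, p_A−p_AB, p_B−p_AB, 1−p_A−p_B+p_AB)` with
`D = D′_target × Dmax` are scaled by the haplotype count and rounded by
largest remainder, conserving the total. Targets whose cell counts are
integral are therefore recovered *exactly* by the LD engine, which is
what makes sharp analytic acceptance tests possible. All randomness flows
through one seed, with per-purpose substreams derived by CRC-hashing the
purpose string, so every emitted file is byte-identical across runs.

## Numerical choices and problem sizes

Breakpoint averaging rounds half-up; largest-remainder rounding conserves
haplotype counts; D′ and r² are clipped at 1 to absorb float excursions
above the analytic bound; −log10(p) caps at 300. The test suite runs the
pipeline at desk scale — tens of truth SVs, up to a few hundred samples,
500 haplotypes for the analytic LD examples — which exercises every code
path in seconds; the algorithms are quadratic in cluster-candidate count
per chromosome at worst and have no cohort-scale assumptions baked in.

## Known limitations

- Biallelic collapse discards multiallelic structure; LD against
  multiallelic SVs may be overestimated (D′ less so than r²).
- Greedy merging and matching are order-dependent on adversarial
  (non-clique / non-path) inputs; determinism is guaranteed by canonical
  sorting, optimality only on the graph classes stated above.
- `refdist` on the minimum of start/end distances approximates, not
  reproduces, Truvari's reference-context model; no sequence comparison
  is performed.
- The annotation module consumes user-supplied tracks; it does not fetch
  UCSC/gnomAD/ClinVar sources and asserts nothing about pathogenicity.
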