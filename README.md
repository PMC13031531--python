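# svld

Structural-variant (SV) catalogs built from long-read cohorts can explain
GWAS association signals that SNPs alone cannot: a GWAS-significant SNP is
often only a *tag* for a nearby deletion, insertion, duplication or
inversion that is the functionally relevant polymorphism. `svld` is the
computational back-end for building such a resource. It takes per-sample SV
calls from multiple callers on two sequencing platforms, merges them into a
consensus population catalog, computes linkage disequilibrium (LD) between
every common SV and GWAS Catalog SNPs from phased haplotypes, joins the
result to trait associations, and benchmarks the call set against reference
SV sets.

It is written for statistical geneticists and bioinformaticians doing
fine-mapping: people who want to ask "is there an SV in high LD with this
GWAS locus?" against their own cohort.

## What it computes

For a biallelic SV (non-reference allele frequency `p_A`) and a biallelic
SNP (alternate allele frequency `p_B`) with joint non-reference haplotype
frequency `p_AB`, counted directly on phased haplotypes:

```
D    = p_AB − p_A p_B
Dmax = min(p_A(1−p_B), (1−p_A)p_B)     if D > 0
       min(p_A p_B, (1−p_A)(1−p_B))    if D < 0
D′   = |D| / Dmax
r²   = D² / (p_A(1−p_A) p_B(1−p_B))
```

`r² ≤ D′²` always holds; both are invariant under allele relabeling.

Around that core:

- **Consensus merging** — a 50% reciprocal-overlap rule for deletions,
  duplications and inversions; insertions match when breakpoints are within
  1,000 bp and lengths within 50% of one another. Merging is anchored
  (pbsv before Sniffles on long reads; Manta before CNVnator, ERDS and
  Long Ranger on linked reads), with PacBio boundaries and genotypes taking
  precedence across platforms, consensus breakpoints averaged over
  constituents, and SVs seen in fewer than three participants removed.
- **Benchmarking** — Truvari-parameterized one-to-one matching
  (`refdist 500 / pctsize 0.7 / pctovl 0.5`), recall stratified by
  non-reference allele frequency (NAF), genotype concordance, and Lin's
  concordance correlation coefficient on paired NAF values with a 95% CI.
- **Annotation** — genomic context (exon > 5′UTR > 3′UTR > intron >
  intergenic), gene-boundary / exon–intron-junction / whole-gene-encompass
  relations, regulatory feature overlap flags, and the per-SV covariate
  table used for feature-overlap association testing.
- **Synthetic fixtures** — a deterministic generator for truth SVs, noisy
  per-caller VCFs, haplotype columns at exact LD targets, GWAS Catalog
  TSVs and feature tracks, so the whole pipeline is testable without any
  downloads.

## Worked example

Construct 500 phased haplotypes on which an SV (NAF 0.114) and a SNP
(AF 0.614) are in maximal positive disequilibrium, then compute the LD
statistics:

```python
from svld import construct_haplotypes, haplotype_frequencies, ld_statistics

a, b = construct_haplotypes(p_a=0.114, p_b=0.614, d_prime_target=1.0,
                            n_haplotypes=500)
p_a, p_b, p_ab, n = haplotype_frequencies(a, b)
d, d_prime, d_sign, r2 = ld_statistics(p_a, p_b, p_ab)
print(f"n={n}  p_a={p_a:.3f}  p_b={p_b:.3f}  p_ab={p_ab:.3f}")
print(f"D={d:.6f}  D'={d_prime:.3f}  r2={r2:.3f}")
```

prints

```
n=500  p_a=0.114  p_b=0.614  p_ab=0.114
D=0.044004  D'=1.000  r2=0.081
```

Every SV-carrying haplotype also carries the SNP allele, so D′ = 1 — the
SNP perfectly tags the SV — while r² stays low (0.081) because the two
allele frequencies differ. This is exactly the signature of a GWAS SNP
tagging an SV of different frequency, the situation the catalog is built
to surface.

The same statistics are available from the shell across whole files:

```sh
svld merge --pacbio-vcfs S000.pbsv.vcf --pacbio-vcfs S000.sniffles.vcf \
           --tenx-vcfs S000.manta.vcf --out merged.vcf
svld ld --merged merged.vcf --phased phased.vcf --gwas gwas_catalog.tsv \
        --out ld.tsv
svld catalog --ld ld.tsv --gwas gwas_catalog.tsv --out catalog.tsv
svld benchmark --base merged.vcf --comp reference.vcf --out report.json
```

`svld simulate --outdir fixtures/` emits a complete synthetic input set to
try the pipeline on.

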