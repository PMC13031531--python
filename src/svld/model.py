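"""Core data model shared across the pipeline.

All genomic intervals are 0-based half-open.  VCF records (1-based,
inclusive) and BED records (already half-open) are converted at the I/O
boundary and nowhere else.

Structural variants are restricted to the four classes the catalog supports
(DEL, INS, DUP, INV).  Breakends and complex events are rejected when read.
Insertions are anchored at a single breakpoint (``end == start + 1``) with
the inserted length carried separately, because caller dialects disagree on
what END means for an insertion.

All variants are treated as biallelic: any non-reference allele collapses
to a single alternate class.  This mirrors the catalog's handling of SVs,
where allele-resolved boundaries cannot be called reliably, and is applied
uniformly to SNPs for consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SUPPORTED_SVTYPES = ("DEL", "INS", "DUP", "INV")

PACBIO_CALLERS = ("pbsv", "sniffles")
TENX_CALLERS = ("manta", "cnvnator", "erds", "longranger")
ALL_CALLERS = PACBIO_CALLERS + TENX_CALLERS

PLATFORM_OF_CALLER = {c: "pacbio_clr" for c in PACBIO_CALLERS}
PLATFORM_OF_CALLER.update({c: "tenx_linked" for c in TENX_CALLERS})

_MAIN_CHROMS = tuple(f"chr{c}" for c in list(range(1, 23)) + ["X", "Y"])


def normalize_chrom(chrom: str) -> str | None:
    """Map a contig name to its chr-prefixed form.

    Returns None for contigs outside chr1-22, chrX, chrY (alternative
    contigs, decoys, unplaced scaffolds), which the pipeline drops.
    """
    name = chrom if chrom.startswith("chr") else f"chr{chrom}"
    if name == "chr23":
        name = "chrX"
    elif name == "chr24":
        name = "chrY"
    return name if name in _MAIN_CHROMS else None


def parse_genotype(gt: str) -> tuple[tuple[int | None, int | None], bool]:
    """Split a VCF GT string into two allele codes and a phased flag.

    Allele indices above 1 collapse to 1 (single non-reference class);
    missing alleles become None.
    """
    phased = "|" in gt
    parts = gt.replace("|", "/").split("/")
    if len(parts) == 1:  # haploid record; duplicate the allele
        parts = parts * 2
    if len(parts) != 2:
        raise ValueError(f"cannot parse genotype {gt!r}")
    alleles = tuple(
        None if p in (".", "") else min(int(p), 1) for p in parts
    )
    return alleles, phased  # type: ignore[return-value]


def genotype_class(gt: str) -> str:
    """Unphased genotype class: '0/0', '0/1', '1/1' or './.'.

    Any genotype with a missing allele is classed missing.
    """
    (a, b), _ = parse_genotype(gt)
    if a is None or b is None:
        return "./."
    a, b = sorted((a, b))
    return f"{a}/{b}"


def is_carrier(gt: str) -> bool:
    """True when the genotype carries at least one non-reference allele."""
    (a, b), _ = parse_genotype(gt)
    return (a == 1) or (b == 1)


@dataclass
class SVCall:
    """A single caller's SV call for one sample."""

    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    genotype: str
    sample_id: str
    caller: str
    platform: str
    source_record_id: str = ""

    def __post_init__(self) -> None:
        if self.svtype not in SUPPORTED_SVTYPES:
            raise ValueError(f"unsupported SVTYPE {self.svtype!r}")
        if self.end < self.start:
            raise ValueError(
                f"end < start for {self.chrom}:{self.start}-{self.end}"
            )
        if self.svtype == "INS":
            if self.end - self.start > 1:
                raise ValueError("INS must be breakpoint-anchored")
            if self.length <= 0:
                raise ValueError("INS requires positive SVLEN")
        elif self.length != self.end - self.start:
            raise ValueError(
                f"{self.svtype} length {self.length} != span "
                f"{self.end - self.start}"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class GwasAssociation:
    """One GWAS Catalog SNP-trait association."""

    rsid: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    trait: str
    pvalue: float
    study_id: str

    def __post_init__(self) -> None:
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"p-value {self.pvalue} outside (0, 1]")
        if self.pos < 1:
            raise ValueError("position must be >= 1")


@dataclass(frozen=True)
class FeatureInterval:
    """A genomic feature interval (BED semantics, half-open)."""

    chrom: str
    start: int
    end: int
    feature_class: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("feature interval must be non-empty")


@dataclass
class HaplotypeMatrix:
    """Phased biallelic alleles: variants x samples x 2 haplotypes.

    ``alleles`` holds int8 codes: 0 reference, 1 non-reference, -1 missing.
    Variant metadata (chrom / pos / ref / alt) is carried in parallel
    arrays so downstream stages can window and join without re-reading the
    VCF.  ``pos`` is 1-based, as in the source VCF.
    """

    variant_ids: list[str]
    sample_ids: list[str]
    alleles: np.ndarray
    chroms: list[str] = field(default_factory=list)
    positions: list[int] = field(default_factory=list)
    refs: list[str] = field(default_factory=list)
    alts: list[str] = field(default_factory=list)

    MISSING = -1

    def __post_init__(self) -> None:
        expected = (len(self.variant_ids), len(self.sample_ids), 2)
        if tuple(self.alleles.shape) != expected:
            raise ValueError(
                f"allele array shape {self.alleles.shape} != {expected}"
            )

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.sample_ids)

    def column(self, variant_id: str) -> np.ndarray:
        """Flat haplotype column (length 2 * n_samples) for one variant."""
        idx = self.variant_ids.index(variant_id)
        return self.alleles[idx].reshape(-1)


@dataclass
class LDResult:
    """Linkage disequilibrium between one SV and one SNP.

    ``d_prime`` is the magnitude |D|/Dmax in [0, 1]; the sign of D is
    carried separately in ``d_sign`` so that the catalog's "D' >= t"
    threshold semantics apply to the magnitude.
    """

    sv_id: str
    snp_id: str
    snp_chrom: str
    snp_pos: int  # 1-based
    snp_ref: str
    snp_alt: str
    p_a: float  # SV non-reference allele frequency on the haplotypes used
    p_b: float  # SNP alternate allele frequency
    p_ab: float  # joint non-reference haplotype frequency
    d: float
    d_prime: float
    d_sign: int
    r2: float
    n_haplotypes: int


@dataclass
class CatalogEntry(LDResult):
    """An LD result joined to a GWAS Catalog association."""

    trait: str = ""
    study_id: str = ""
    gwas_pvalue: float = 1.0
    neg_log10_p: float = 0.0
    snp_genomic_context: str = "intergenic"
    sv_genomic_context: str = "intergenic"


@dataclass
class MergedSV:
    """Consensus SV across callers, platforms and samples."""

    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    genotypes: dict[str, str] = field(default_factory=dict)
    provenance: list[tuple[str, str, str, int, int, int]] = field(
        default_factory=list
    )  # (sample, caller, platform, start, end, length)

    @property
    def sv_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.svtype}"

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def carrier_count(self) -> int:
        return sum(1 for gt in self.genotypes.values() if is_carrier(gt))

    @property
    def naf(self) -> float:
        """Non-reference allele frequency over non-missing haplotypes."""
        nonref = total = 0
        for gt in self.genotypes.values():
            (a, b), _ = parse_genotype(gt)
            for allele in (a, b):
                if allele is not None:
                    total += 1
                    nonref += allele
        return nonref / total if total else 0.0
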