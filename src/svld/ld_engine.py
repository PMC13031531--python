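"""Linkage disequilibrium between SVs and SNPs from phased haplotypes.

For a pair of biallelic loci with non-reference allele frequencies
``p_a`` (SV) and ``p_b`` (SNP) and joint non-reference haplotype frequency
``p_ab``:

    D       = p_ab - p_a * p_b
    Dmax    = min(p_a (1 - p_b), (1 - p_a) p_b)      if D > 0
              min(p_a p_b, (1 - p_a)(1 - p_b))       if D < 0
    D'      = |D| / Dmax                              (0 when D == 0)
    r^2     = D^2 / (p_a (1 - p_a) p_b (1 - p_b))

Statistics are obtained by direct counting on phased haplotypes;
haplotypes missing at either locus are excluded pairwise.  D' is reported
as a magnitude in [0, 1] with the sign of D carried separately, so that
"D' >= 0.8"-style thresholds read naturally.  r^2 <= D'^2 always holds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import HaplotypeMatrix, LDResult, MergedSV

logger = logging.getLogger(__name__)


@dataclass
class LDWindowConfig:
    window_bp: int = 1_000_000
    gwas_p_threshold: float = 1e-6
    sv_maf_min: float = 0.1

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        for t in (self.gwas_p_threshold, self.sv_maf_min):
            if not (0 < t < 1):
                raise ValueError("thresholds must lie in (0, 1)")


class MonomorphicError(ValueError):
    """Raised when a locus has no variation on the retained haplotypes."""


def haplotype_frequencies(
    sv_alleles: np.ndarray, snp_alleles: np.ndarray
) -> tuple[float, float, float, int]:
    """Allele and joint haplotype frequencies for one SV-SNP pair.

    Haplotypes with a missing allele at either locus are excluded
    pairwise; frequencies are computed on the remainder.
    """
    a = np.asarray(sv_alleles).reshape(-1)
    b = np.asarray(snp_alleles).reshape(-1)
    if a.shape != b.shape:
        raise ValueError("haplotype columns differ in length")
    keep = (a != HaplotypeMatrix.MISSING) & (b != HaplotypeMatrix.MISSING)
    a, b = a[keep], b[keep]
    n = int(a.size)
    if n == 0:
        raise MonomorphicError("no haplotypes remain after missing-data exclusion")
    p_a = float(np.mean(a == 1))
    p_b = float(np.mean(b == 1))
    p_ab = float(np.mean((a == 1) & (b == 1)))
    return p_a, p_b, p_ab, n


def ld_statistics(p_a: float, p_b: float, p_ab: float) -> tuple[float, float, int, float]:
    """(D, D', sign(D), r^2) from allele and joint frequencies.

    Both loci must be polymorphic (frequencies strictly inside (0, 1));
    monomorphic pairs are undefined, not zero.
    """
    if not (0 < p_a < 1) or not (0 < p_b < 1):
        raise MonomorphicError(
            f"LD undefined for monomorphic locus (p_a={p_a}, p_b={p_b})"
        )
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(d) / d_max if d != 0 else 0.0
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    d_sign = 1 if d > 0 else (-1 if d < 0 else 0)
    # clip tiny floating excursions above the analytic bounds
    return d, min(d_prime, 1.0), d_sign, min(r2, 1.0)


def _sv_distance(sv: MergedSV, snp_pos_1based: int) -> int:
    """bp from a SNP to the nearest SV edge (breakpoint for insertions)."""
    pos = snp_pos_1based - 1  # 0-based point
    if sv.svtype == "INS":
        lo, hi = sv.start, sv.start + 1
    else:
        lo, hi = sv.start, sv.end
    if pos < lo:
        return lo - pos
    if pos >= hi:
        return pos - hi + 1
    return 0


def pair_sv_snps(
    svs: list[MergedSV],
    snps: HaplotypeMatrix,
    cfg: LDWindowConfig,
) -> list[tuple[MergedSV, int]]:
    """All (SV, SNP index) pairs within the LD window on the same chromosome.

    The SNP set is assumed already restricted to GWAS-significant
    variants, and the SV set to common SVs (MAF-filtered); this function
    only applies the positional window.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, chrom in enumerate(snps.chroms):
        by_chrom.setdefault(chrom, []).append(i)
    pairs: list[tuple[MergedSV, int]] = []
    for sv in sorted(svs, key=lambda s: (s.chrom, s.start, s.end, s.svtype)):
        for i in by_chrom.get(sv.chrom, []):
            if _sv_distance(sv, snps.positions[i]) <= cfg.window_bp:
                pairs.append((sv, i))
    return pairs


def ld_scan(
    svs: list[MergedSV],
    haplotypes: HaplotypeMatrix,
    cfg: LDWindowConfig | None = None,
    snp_ids: list[str] | None = None,
) -> list[LDResult]:
    """LD between every qualifying SV and every SNP within the window.

    SVs are looked up in the phased matrix by their ``sv_id``; a missing
    SV is fatal.  SVs outside the MAF band [maf_min, 1 - maf_min] are
    skipped; monomorphic pairs are dropped with a logged count.  SNP
    columns are the matrix variants named in ``snp_ids`` (default: every
    variant that is not one of the supplied SVs).
    """
    cfg = cfg or LDWindowConfig()
    index = {vid: i for i, vid in enumerate(haplotypes.variant_ids)}
    sv_ids = {sv.sv_id for sv in svs}
    if snp_ids is None:
        snp_ids = [vid for vid in haplotypes.variant_ids if vid not in sv_ids]
    snp_set = set(snp_ids)

    snp_matrix = HaplotypeMatrix(
        variant_ids=[v for v in haplotypes.variant_ids if v in snp_set],
        sample_ids=haplotypes.sample_ids,
        alleles=haplotypes.alleles[[i for i, v in enumerate(haplotypes.variant_ids) if v in snp_set]],
        chroms=[haplotypes.chroms[i] for i, v in enumerate(haplotypes.variant_ids) if v in snp_set],
        positions=[haplotypes.positions[i] for i, v in enumerate(haplotypes.variant_ids) if v in snp_set],
        refs=[haplotypes.refs[i] for i, v in enumerate(haplotypes.variant_ids) if v in snp_set],
        alts=[haplotypes.alts[i] for i, v in enumerate(haplotypes.variant_ids) if v in snp_set],
    )

    usable: list[MergedSV] = []
    for sv in svs:
        if sv.sv_id not in index:
            raise KeyError(f"SV {sv.sv_id} absent from the phased haplotype matrix")
        maf = min(sv.naf, 1 - sv.naf)
        if maf >= cfg.sv_maf_min:
            usable.append(sv)

    results: list[LDResult] = []
    n_undefined = 0
    for sv, snp_i in pair_sv_snps(usable, snp_matrix, cfg):
        sv_col = haplotypes.alleles[index[sv.sv_id]].reshape(-1)
        snp_col = snp_matrix.alleles[snp_i].reshape(-1)
        try:
            p_a, p_b, p_ab, n = haplotype_frequencies(sv_col, snp_col)
            d, d_prime, d_sign, r2 = ld_statistics(p_a, p_b, p_ab)
        except MonomorphicError:
            n_undefined += 1
            continue
        results.append(
            LDResult(
                sv_id=sv.sv_id,
                snp_id=snp_matrix.variant_ids[snp_i],
                snp_chrom=snp_matrix.chroms[snp_i],
                snp_pos=snp_matrix.positions[snp_i],
                snp_ref=snp_matrix.refs[snp_i],
                snp_alt=snp_matrix.alts[snp_i],
                p_a=p_a,
                p_b=p_b,
                p_ab=p_ab,
                d=d,
                d_prime=d_prime,
                d_sign=d_sign,
                r2=r2,
                n_haplotypes=n,
            )
        )
    if n_undefined:
        logger.info("ld_scan: dropped %d monomorphic pairs", n_undefined)
    results.sort(key=lambda r: (r.snp_chrom, r.sv_id, r.snp_pos, r.snp_id))
    return results
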