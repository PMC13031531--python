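"""Join LD results to GWAS Catalog associations and build catalog tables.

The join key is the SNP's genomic position plus its reference and
alternate alleles.  Strict mode requires both alleles to agree; lenient
mode (``allele_strict=False``) joins on position and rsid alone, for
catalog rows whose risk allele is unreported.  A SNP associated with k
traits contributes k catalog entries.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .model import CatalogEntry, GwasAssociation, LDResult, MergedSV

logger = logging.getLogger(__name__)

NEG_LOG10_P_CAP = 300.0  # survives underflowed catalog p-values

CONTEXTS = ("intergenic", "exon", "intron", "5'UTR", "3'UTR", "up/downstream")


def _neg_log10(p: float) -> float:
    if p <= 0:
        return NEG_LOG10_P_CAP
    return min(-math.log10(p), NEG_LOG10_P_CAP)


def join_gwas(
    ld: list[LDResult],
    assoc: list[GwasAssociation],
    allele_strict: bool = True,
    contexts_by_sv: dict[str, str] | None = None,
    contexts_by_snp: dict[str, str] | None = None,
) -> list[CatalogEntry]:
    """Inner join of LD results with GWAS Catalog associations.

    Strict mode keys on (chrom, pos, ref, alt); lenient mode on
    (chrom, pos) with the rsid as tie-breaker when the LD result carries
    one.  Unmatched LD rows are logged.  Genomic contexts, when supplied,
    are attached per sv_id / snp_id.
    """
    by_key: dict[tuple, list[GwasAssociation]] = defaultdict(list)
    for a in assoc:
        if allele_strict:
            by_key[(a.chrom, a.pos, a.ref_allele, a.alt_allele)].append(a)
        else:
            by_key[(a.chrom, a.pos)].append(a)

    contexts_by_sv = contexts_by_sv or {}
    contexts_by_snp = contexts_by_snp or {}
    entries: list[CatalogEntry] = []
    n_unmatched = 0
    for r in ld:
        if allele_strict:
            key = (r.snp_chrom, r.snp_pos, r.snp_ref, r.snp_alt)
        else:
            key = (r.snp_chrom, r.snp_pos)
        matches = by_key.get(key, [])
        if not allele_strict and matches and r.snp_id.startswith("rs"):
            named = [a for a in matches if a.rsid == r.snp_id]
            if named:
                matches = named
        if not matches:
            n_unmatched += 1
            continue
        seen_alleles = {(a.ref_allele, a.alt_allele) for a in matches}
        if len(seen_alleles) > 1:
            logger.warning(
                "conflicting ref/alt among associations at %s:%d; joining all",
                r.snp_chrom,
                r.snp_pos,
            )
        for a in matches:
            entries.append(
                CatalogEntry(
                    **{k: getattr(r, k) for k in LDResult.__dataclass_fields__},
                    trait=a.trait,
                    study_id=a.study_id,
                    gwas_pvalue=a.pvalue,
                    neg_log10_p=_neg_log10(a.pvalue),
                    snp_genomic_context=contexts_by_snp.get(r.snp_id, "intergenic"),
                    sv_genomic_context=contexts_by_sv.get(r.sv_id, "intergenic"),
                )
            )
    if n_unmatched:
        logger.info("join_gwas: %d LD rows had no catalog association", n_unmatched)
    return entries


@dataclass
class SVSummary:
    """Per-SV maxima over catalog entries."""

    sv_id: str
    max_d_prime: float
    max_r2: float
    n_associated_traits: int
    n_gwas_snps_in_window: int


def sv_summaries(entries: list[CatalogEntry]) -> list[SVSummary]:
    """Per-SV max LD and association counts; SVs with no entries are absent."""
    by_sv: dict[str, list[CatalogEntry]] = defaultdict(list)
    for e in entries:
        by_sv[e.sv_id].append(e)
    out = []
    for sv_id in sorted(by_sv):
        es = by_sv[sv_id]
        out.append(
            SVSummary(
                sv_id=sv_id,
                max_d_prime=max(e.d_prime for e in es),
                max_r2=max(e.r2 for e in es),
                n_associated_traits=len({e.trait for e in es}),
                n_gwas_snps_in_window=len({e.snp_id for e in es}),
            )
        )
    return out


def stratified_counts(
    svs: list[MergedSV],
    summaries: list[SVSummary],
    contexts_by_sv: dict[str, str],
    thresholds: tuple[float | None, ...] = (None, 0.5, 0.8),
) -> pd.DataFrame:
    """SV counts by type x genomic context x max-D' threshold.

    Rows are (svtype, threshold) with threshold None labelled "all"
    (every SV of the type regardless of LD); columns are the genomic
    contexts plus a row total.  For a numeric threshold t the cell counts
    SVs whose max D' over catalog entries is >= t (SVs without entries
    never qualify).
    """
    max_dp = {s.sv_id: s.max_d_prime for s in summaries}
    rows = []
    for svtype in ("INS", "DEL", "DUP", "INV"):
        typed = [sv for sv in svs if sv.svtype == svtype]
        for t in thresholds:
            label = "all" if t is None else f"D'>={t}"
            counts = {ctx: 0 for ctx in CONTEXTS}
            for sv in typed:
                if t is not None and max_dp.get(sv.sv_id, 0.0) < t:
                    continue
                ctx = contexts_by_sv.get(sv.sv_id, "intergenic")
                counts[ctx] = counts.get(ctx, 0) + 1
            row = {"svtype": svtype, "threshold": label, **counts}
            row["total"] = sum(counts.values())
            rows.append(row)
    df = pd.DataFrame(rows, columns=["svtype", "threshold", *CONTEXTS, "total"])
    return df.set_index(["svtype", "threshold"])


def plot_data(
    entries: list[CatalogEntry],
    sv_id: str,
    trait: str | None = None,
) -> list[dict]:
    """Plot-ready records for one SV's locus view.

    Without a trait, one record per catalog entry with the SNP position
    on x and the LD statistics on y.  With a trait, records carry
    -log10(p) as the y-value and LD as the color value; entries for other
    traits are flagged ``background`` (the gray dots of the locus view).
    """
    mine = [e for e in entries if e.sv_id == sv_id]
    if not mine:
        logger.warning("plot_data: no catalog entries for SV %s", sv_id)
        return []
    mine.sort(key=lambda e: (e.snp_pos, e.snp_id, e.trait, e.study_id))
    records = []
    for e in mine:
        rec = {
            "snp_id": e.snp_id,
            "snp_pos": e.snp_pos,
            "d_prime": e.d_prime,
            "r2": e.r2,
            "trait": e.trait,
        }
        if trait is not None:
            rec["neg_log10_p"] = e.neg_log10_p
            rec["background"] = e.trait != trait
        records.append(rec)
    return records
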