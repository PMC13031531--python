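"""Genomic context, feature overlaps and the per-SV covariate table.

Context uses the catalog's six-class vocabulary (intergenic, exon,
intron, 5'UTR, 3'UTR, up/downstream) with gene-proximal precedence:
exon > 5'UTR > 3'UTR > intron > intergenic.  Gene relations record
whether an SV disturbs a gene boundary (start/stop), crosses an
exon-intron junction (a splice-site risk), or swallows whole genes.

Feature overlap uses a >= 1 bp threshold over interval-indexed tracks;
a TAD boundary is flagged only when the SV actually crosses a block edge
(extends strictly on both sides of it).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .model import FeatureInterval, GwasAssociation, MergedSV
from .catalog import SVSummary
from .ld_engine import _sv_distance

CONTEXT_PRECEDENCE = ("exon", "5'UTR", "3'UTR", "intron", "intergenic")

GENE_CLASSES = {"gene", "exon", "5'UTR", "3'UTR"}


@dataclass
class AnnotationRecord:
    sv_id: str
    genomic_context: str
    overlaps: set[str] = field(default_factory=set)
    gene_relation: str = "none"
    encompassed_gene_count: int = 0


@dataclass
class CovariateRow:
    """One row of the design matrix for feature-overlap association tests."""

    sv_id: str
    naf: float
    svtype: str
    length_bp: int
    n_gwas_snps_in_window: int
    max_d_prime: float
    max_r2: float
    indicators: dict[str, int] = field(default_factory=dict)


def _overlaps(sv: MergedSV, feat: FeatureInterval) -> bool:
    lo, hi = sv.start, max(sv.end, sv.start + 1)
    return feat.chrom == sv.chrom and lo < feat.end and feat.start < hi


def assign_context(
    sv: MergedSV, gene_models: list[FeatureInterval]
) -> tuple[str, str, int]:
    """(genomic_context, gene_relation, encompassed_gene_count) for one SV.

    ``gene_models`` mixes intervals of class gene / exon / 5'UTR / 3'UTR,
    one transcript per gene (MANE-style).  Introns are gene minus its
    sub-features, so an SV in a gene touching no exon or UTR is intronic.
    """
    hit_classes: set[str] = set()
    genes_hit: list[FeatureInterval] = []
    exons_by_gene: dict[str, list[FeatureInterval]] = defaultdict(list)
    for feat in gene_models:
        if feat.feature_class == "exon":
            exons_by_gene[feat.name].append(feat)
        if not _overlaps(sv, feat):
            continue
        hit_classes.add(feat.feature_class)
        if feat.feature_class == "gene":
            genes_hit.append(feat)

    if "gene" in hit_classes:
        hit_classes.add("intron")  # refined away below if a sub-feature hit
    context = "intergenic"
    for cls in CONTEXT_PRECEDENCE:
        if cls in hit_classes:
            context = cls
            break

    encompassed = [
        g for g in genes_hit if sv.start <= g.start and max(sv.end, sv.start + 1) >= g.end
    ]
    lo, hi = sv.start, max(sv.end, sv.start + 1)
    crosses_junction = False
    touches_boundary = False
    contained = False
    for g in genes_hit:
        # gene start/stop bases are g.start and g.end - 1 (half-open)
        if lo <= g.start < hi or lo <= g.end - 1 < hi:
            touches_boundary = True
        if lo >= g.start and hi <= g.end:
            contained = True
        for exon in exons_by_gene.get(g.name, []):
            for junction in (exon.start, exon.end):
                if g.start < junction < g.end and lo < junction < hi:
                    crosses_junction = True

    if encompassed:
        relation = "full_gene_encompass"
    elif crosses_junction:
        relation = "exon_intron_boundary"
    elif touches_boundary:
        relation = "gene_boundary"
    elif contained:
        relation = "contained"
    else:
        relation = "none"
    return context, relation, len(encompassed)


def overlap_flags(
    sv: MergedSV, tracks: dict[str, list[FeatureInterval]]
) -> set[str]:
    """Feature classes the SV overlaps by >= 1 bp.

    The TAD_block track additionally yields TAD_boundary when the SV
    crosses a block edge.
    """
    flags: set[str] = set()
    lo, hi = sv.start, max(sv.end, sv.start + 1)
    for cls, feats in tracks.items():
        for feat in feats:
            if not _overlaps(sv, feat):
                continue
            flags.add(cls)
            if cls == "TAD_block":
                for edge in (feat.start, feat.end):
                    if lo < edge < hi:
                        flags.add("TAD_boundary")
    return flags


def annotate_svs(
    svs: list[MergedSV],
    gene_models: list[FeatureInterval],
    tracks: dict[str, list[FeatureInterval]] | None = None,
) -> list[AnnotationRecord]:
    """Context + overlap annotation for a call set."""
    tracks = tracks or {}
    # index tracks once; assign_context scans gene models per SV, which is
    # adequate at catalog scale with per-chromosome pre-binning
    genes_by_chrom: dict[str, list[FeatureInterval]] = defaultdict(list)
    for feat in gene_models:
        genes_by_chrom[feat.chrom].append(feat)
    trees: dict[str, dict[str, IntervalTree]] = {}
    for cls, feats in tracks.items():
        per_chrom: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for f in feats:
            per_chrom[f.chrom].addi(f.start, f.end, f)
        trees[cls] = per_chrom

    records = []
    for sv in svs:
        context, relation, n_genes = assign_context(sv, genes_by_chrom[sv.chrom])
        lo, hi = sv.start, max(sv.end, sv.start + 1)
        flags: set[str] = set()
        for cls, per_chrom in trees.items():
            hits = per_chrom[sv.chrom].overlap(lo, hi)
            if hits:
                flags.add(cls)
                if cls == "TAD_block":
                    for iv in hits:
                        for edge in (iv.begin, iv.end):
                            if lo < edge < hi:
                                flags.add("TAD_boundary")
        records.append(
            AnnotationRecord(
                sv_id=sv.sv_id,
                genomic_context=context,
                overlaps=flags,
                gene_relation=relation,
                encompassed_gene_count=n_genes,
            )
        )
    return records


def build_covariate_table(
    svs: list[MergedSV],
    annotations: list[AnnotationRecord],
    ld_summaries: list[SVSummary],
    gwas_snps: list[GwasAssociation],
    window_bp: int = 1_000_000,
    feature_classes: tuple[str, ...] = (
        "enhancer",
        "promoter",
        "CpG_island",
        "repeat",
        "segdup",
        "TAD_block",
        "TAD_boundary",
    ),
) -> list[CovariateRow]:
    """Per-SV covariate rows for regulatory-feature association testing.

    One row per SV (missing annotation is fatal, no silent drops);
    ``n_gwas_snps_in_window`` counts distinct catalog SNP positions within
    the LD window of the SV, max LD fields are 0 when the SV had no pairs.
    """
    anno_by_sv = {a.sv_id: a for a in annotations}
    summ_by_sv = {s.sv_id: s for s in ld_summaries}
    snps_by_chrom: dict[str, list[int]] = defaultdict(list)
    for a in gwas_snps:
        snps_by_chrom[a.chrom].append(a.pos)

    rows = []
    for sv in svs:
        anno = anno_by_sv.get(sv.sv_id)
        if anno is None:
            raise KeyError(f"no annotation for SV {sv.sv_id}")
        summ = summ_by_sv.get(sv.sv_id)
        n_snps = len(
            {
                pos
                for pos in snps_by_chrom.get(sv.chrom, [])
                if _sv_distance(sv, pos) <= window_bp
            }
        )
        rows.append(
            CovariateRow(
                sv_id=sv.sv_id,
                naf=sv.naf,
                svtype=sv.svtype,
                length_bp=sv.length,
                n_gwas_snps_in_window=n_snps,
                max_d_prime=summ.max_d_prime if summ else 0.0,
                max_r2=summ.max_r2 if summ else 0.0,
                indicators={cls: int(cls in anno.overlaps) for cls in feature_classes},
            )
        )
    return rows
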