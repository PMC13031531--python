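"""Read and write the standard formats the pipeline touches.

Caller dialects are normalized into the internal data model at this
boundary: symbolic ALT alleles (<DEL>, <INS>, <DUP>, <INV>) and explicit
REF/ALT indel-style records both become :class:`~svld.model.SVCall`, VCF
1-based positions become 0-based half-open intervals, and SVLEN signs are
normalized to positive.  Breakends, translocations and complex events are
skipped with a logged count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .model import (
    SUPPORTED_SVTYPES,
    CatalogEntry,
    FeatureInterval,
    GwasAssociation,
    HaplotypeMatrix,
    MergedSV,
    SVCall,
    normalize_chrom,
    parse_genotype,
)

logger = logging.getLogger(__name__)

_SYMBOLIC = {f"<{t}>": t for t in SUPPORTED_SVTYPES}


def _gt_string(sample) -> str:
    alleles = sample.get("GT", (None,))
    if alleles is None:
        alleles = (None,)
    sep = "|" if sample.phased else "/"
    return sep.join("." if a is None else str(a) for a in alleles)


def _classify_record(rec) -> str | None:
    """SVTYPE of a VCF record, or None when unsupported/unclassifiable."""
    svtype = rec.info.get("SVTYPE")
    if svtype is not None:
        svtype = str(svtype)
        return svtype if svtype in SUPPORTED_SVTYPES else None
    alt = rec.alts[0] if rec.alts else None
    if alt is None:
        return None
    if alt in _SYMBOLIC:
        return _SYMBOLIC[alt]
    if alt.startswith("<") or "[" in alt or "]" in alt:
        return None  # other symbolic allele or breakend
    # explicit indel-style record
    if len(rec.ref) > len(alt):
        return "DEL"
    if len(alt) > len(rec.ref):
        return "INS"
    return None


def _svlen(rec) -> int | None:
    svlen = rec.info.get("SVLEN")
    if svlen is None:
        return None
    if isinstance(svlen, (tuple, list)):
        svlen = svlen[0]
    return abs(int(svlen))


def read_sv_vcf(path, caller: str, platform: str) -> list[SVCall]:
    """Read one caller's VCF into normalized SV calls.

    One :class:`SVCall` is emitted per sample that carries a non-reference
    allele at the record (callers emit per-sample evidence; hom-ref and
    fully missing sample entries are not calls).  Records whose SVTYPE is
    unsupported (BND, CPX, ...), whose contig falls outside chr1-22/X/Y,
    or which lack both END and SVLEN for a non-INS symbolic allele are
    skipped with a logged count.
    """
    calls: list[SVCall] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            chrom = normalize_chrom(rec.chrom)
            svtype = _classify_record(rec)
            if chrom is None or svtype is None:
                n_skipped += 1
                continue
            symbolic = bool(rec.alts) and rec.alts[0].startswith("<")
            svlen = _svlen(rec)
            if svtype == "INS":
                start = rec.start
                end = start + 1
                length = svlen if svlen is not None else len(rec.alts[0]) - len(rec.ref)
                if length is None or length <= 0:
                    n_skipped += 1
                    logger.warning("INS at %s:%d lacks a usable length", rec.chrom, rec.pos)
                    continue
            elif symbolic:
                start = rec.start
                # SVLEN, when present, defines the span from the 0-based
                # start; otherwise END does (pysam folds END into rec.stop,
                # which stays at start + len(REF) when END was absent)
                if svlen is not None:
                    end = start + svlen
                elif rec.stop > rec.start + len(rec.ref):
                    end = rec.stop
                else:
                    n_skipped += 1
                    logger.warning(
                        "record at %s:%d rejected: no END and no SVLEN", rec.chrom, rec.pos
                    )
                    continue
                length = end - start
            else:
                # explicit REF/ALT deletion: padding base at POS, event after it
                start = rec.start + 1
                end = rec.start + len(rec.ref)
                length = end - start
            if end < start or (svtype != "INS" and length <= 0):
                n_skipped += 1
                continue
            rec_id = rec.id or f"{rec.chrom}:{rec.pos}"
            single_sample = len(rec.samples) == 1
            for sample_name in rec.samples:
                gt = _gt_string(rec.samples[sample_name])
                (a, b), _ = parse_genotype(gt)
                # single-sample caller output: every record is that sample's
                # call; multi-sample: a call exists only for carrier samples
                if not single_sample and not (a == 1 or b == 1):
                    continue
                calls.append(
                    SVCall(
                        chrom=chrom,
                        start=start,
                        end=end,
                        svtype=svtype,
                        length=length,
                        genotype=gt,
                        sample_id=sample_name,
                        caller=caller,
                        platform=platform,
                        source_record_id=rec_id,
                    )
                )
    if n_skipped:
        logger.info("read_sv_vcf(%s): skipped %d unsupported records", path, n_skipped)
    return calls


def read_phased_vcf(path) -> HaplotypeMatrix:
    """Read a phased multi-sample VCF into a haplotype matrix.

    Every non-missing heterozygous genotype must be phased ('|');
    an unphased het is fatal and names the offending locus.  ALT allele
    indices above 1 collapse to a single non-reference class.
    """
    variant_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        for rec in vf:
            chrom = normalize_chrom(rec.chrom)
            if chrom is None:
                continue
            row = []
            for name in sample_ids:
                sample = rec.samples[name]
                gt = _gt_string(sample)
                (a, b), phased = parse_genotype(gt)
                if a is not None and b is not None and a != b and not phased:
                    raise ValueError(
                        f"unphased heterozygous genotype {gt!r} for sample "
                        f"{name} at {rec.chrom}:{rec.pos}"
                    )
                row.append(
                    (
                        HaplotypeMatrix.MISSING if a is None else a,
                        HaplotypeMatrix.MISSING if b is None else b,
                    )
                )
            vid = rec.id or f"{chrom}:{rec.pos}:{rec.ref}:{rec.alts[0] if rec.alts else '.'}"
            variant_ids.append(vid)
            chroms.append(chrom)
            positions.append(rec.pos)
            refs.append(rec.ref or "N")
            alts.append(rec.alts[0] if rec.alts else ".")
            rows.append(row)
    alleles = np.array(rows, dtype=np.int8).reshape(len(rows), len(sample_ids), 2)
    return HaplotypeMatrix(
        variant_ids=variant_ids,
        sample_ids=sample_ids,
        alleles=alleles,
        chroms=chroms,
        positions=positions,
        refs=refs,
        alts=alts,
    )


_GWAS_REQUIRED = ["CHR_ID", "CHR_POS", "SNPS", "P-VALUE", "DISEASE/TRAIT"]


def read_gwas_catalog_tsv(
    path,
    p_threshold: float = 1e-6,
    split_multi_snp: bool = False,
) -> list[GwasAssociation]:
    """Parse a GWAS Catalog v1.0 associations TSV.

    Rows with unparsable position or p-value are dropped with a logged
    count, as are rows at or above ``p_threshold``.  Rows mapping to
    several SNPs (haplotype or interaction entries, ';'-separated) are
    dropped by default or split per SNP when ``split_multi_snp`` is set.

    The catalog dialect has no REF/ALT columns; the alternate allele is
    taken from the STRONGEST SNP-RISK ALLELE suffix, and optional
    REF_ALLELE / ALT_ALLELE columns (written by the synthetic generator
    and by annotation pipelines) take precedence when present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _GWAS_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS Catalog TSV missing required columns: {missing}")

    out: list[GwasAssociation] = []
    n_dropped = 0
    for _, row in df.iterrows():
        raw_chr = row["CHR_ID"].strip()
        raw_pos = row["CHR_POS"].strip()
        raw_snp = row["SNPS"].strip()
        risk = row.get("STRONGEST SNP-RISK ALLELE", "").strip()
        study = row.get("STUDY ACCESSION", "").strip() or "NA"
        trait = row["DISEASE/TRAIT"].strip()
        try:
            pvalue = float(row["P-VALUE"])
        except ValueError:
            n_dropped += 1
            continue
        if not (0 < pvalue <= 1) or pvalue >= p_threshold:
            n_dropped += 1
            continue

        multi = ";" in raw_snp or " x " in raw_snp
        if multi and not split_multi_snp:
            n_dropped += 1
            continue
        if multi:
            snps = [s.strip() for s in raw_snp.split(";")]
            chrs = [s.strip() for s in raw_chr.split(";")]
            poss = [s.strip() for s in raw_pos.split(";")]
            risks = [s.strip() for s in risk.split(";")]
            if not (len(snps) == len(chrs) == len(poss)):
                n_dropped += 1
                continue
            if len(risks) != len(snps):
                risks = [""] * len(snps)
        else:
            snps, chrs, poss, risks = [raw_snp], [raw_chr], [raw_pos], [risk]

        for rsid, chrom_raw, pos_raw, risk_one in zip(snps, chrs, poss, risks):
            chrom = normalize_chrom(chrom_raw) if chrom_raw else None
            try:
                pos = int(pos_raw)
            except ValueError:
                n_dropped += 1
                continue
            if chrom is None or pos < 1:
                n_dropped += 1
                continue
            alt = str(row.get("ALT_ALLELE", "")).strip()
            ref = str(row.get("REF_ALLELE", "")).strip()
            if not alt and "-" in risk_one:
                allele = risk_one.rsplit("-", 1)[1].strip()
                alt = "" if allele in ("?", "") else allele
            out.append(
                GwasAssociation(
                    rsid=rsid,
                    chrom=chrom,
                    pos=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    trait=trait,
                    pvalue=pvalue,
                    study_id=study,
                )
            )
    if n_dropped:
        logger.info("read_gwas_catalog_tsv(%s): dropped %d rows", path, n_dropped)
    return out


def read_bed(path, feature_class: str | None = None) -> list[FeatureInterval]:
    """Read BED 3+/BED 4 into feature intervals.

    With ``feature_class`` unset, the 4th BED column doubles as the class
    (tracks exported one-class-per-file pass the class explicitly and the
    4th column stays the element name).
    """
    feats: list[FeatureInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom = normalize_chrom(parts[0])
            if chrom is None:
                continue
            start, end = int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            feats.append(
                FeatureInterval(
                    chrom=chrom,
                    start=start,
                    end=end,
                    feature_class=feature_class or name or "feature",
                    name=name,
                )
            )
    return feats


# ---------------------------------------------------------------------------
# merged-SV VCF round trip

def write_merged_vcf(svs: list[MergedSV], path, sample_ids: list[str] | None = None) -> None:
    """Write consensus SVs as a symbolic-ALT VCF with provenance INFO tags.

    INFO carries CALLERS, PLATFORMS, SUPP (constituent count), NAF and
    CARRIERS; FORMAT is GT only.
    """
    if sample_ids is None:
        seen: dict[str, None] = {}
        for sv in svs:
            for s in sv.genotypes:
                seen.setdefault(s, None)
        sample_ids = sorted(seen)
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom in sorted({sv.chrom for sv in svs}):
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    header.add_line('##ALT=<ID=INS,Description="Insertion">')
    header.add_line('##ALT=<ID=DUP,Description="Duplication">')
    header.add_line('##ALT=<ID=INV,Description="Inversion">')
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End (1-based inclusive)">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting callers">')
    header.add_line('##INFO=<ID=PLATFORMS,Number=.,Type=String,Description="Supporting platforms">')
    header.add_line('##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Constituent call count">')
    header.add_line('##INFO=<ID=NAF,Number=1,Type=Float,Description="Non-reference allele frequency">')
    header.add_line('##INFO=<ID=CARRIERS,Number=1,Type=Integer,Description="Samples with a non-reference allele">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in sample_ids:
        header.add_sample(s)
    ordered = sorted(svs, key=lambda s: (s.chrom, s.start, s.end, s.svtype))
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for sv in ordered:
            rec = vf.new_record(
                contig=sv.chrom,
                start=sv.start,
                stop=sv.end,
                alleles=("N", f"<{sv.svtype}>"),
            )
            rec.id = sv.sv_id
            rec.info["SVTYPE"] = sv.svtype
            if sv.svtype == "INS":
                # for spanning types END carries the span; SVLEN would make
                # htslib re-derive END under the padding-base convention
                rec.info["SVLEN"] = sv.length
            callers = sorted({p[1] for p in sv.provenance}) or ["."]
            platforms = sorted({p[2] for p in sv.provenance}) or ["."]
            rec.info["CALLERS"] = ",".join(callers)
            rec.info["PLATFORMS"] = ",".join(platforms)
            rec.info["SUPP"] = max(len(sv.provenance), 1)
            rec.info["NAF"] = round(sv.naf, 6)
            rec.info["CARRIERS"] = sv.carrier_count
            for name in sample_ids:
                gt = sv.genotypes.get(name, "0/0")
                (a, b), phased = parse_genotype(gt)
                rec.samples[name]["GT"] = (a, b)
                rec.samples[name].phased = phased
            vf.write(rec)


def read_merged_vcf(path) -> list[MergedSV]:
    """Read a merged-SV VCF written by :func:`write_merged_vcf`."""
    svs: list[MergedSV] = []
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        for rec in vf:
            chrom = normalize_chrom(rec.chrom)
            svtype = str(rec.info["SVTYPE"])
            if chrom is None or svtype not in SUPPORTED_SVTYPES:
                continue
            start = rec.start
            svlen = _svlen(rec)
            if svtype == "INS":
                end = start + 1
                length = svlen if svlen is not None else 0
            else:
                end = rec.stop
                length = end - start
            genotypes = {
                name: _gt_string(rec.samples[name]) for name in sample_ids
            }
            svs.append(
                MergedSV(
                    chrom=chrom,
                    start=start,
                    end=end,
                    svtype=svtype,
                    length=length,
                    genotypes=genotypes,
                )
            )
    return svs


def write_phased_vcf(matrix: HaplotypeMatrix, path) -> None:
    """Write a haplotype matrix as a phased multi-sample VCF.

    Round-trip partner of :func:`read_phased_vcf`.
    """
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    for chrom in sorted(set(matrix.chroms)):
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in matrix.sample_ids:
        header.add_sample(s)
    order = sorted(
        range(matrix.n_variants),
        key=lambda i: (matrix.chroms[i], matrix.positions[i], matrix.variant_ids[i]),
    )
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i in order:
            rec = vf.new_record(
                contig=matrix.chroms[i],
                start=matrix.positions[i] - 1,
                alleles=(matrix.refs[i], matrix.alts[i]),
            )
            rec.id = matrix.variant_ids[i]
            for j, name in enumerate(matrix.sample_ids):
                a, b = matrix.alleles[i, j]
                rec.samples[name]["GT"] = (
                    None if a == HaplotypeMatrix.MISSING else int(a),
                    None if b == HaplotypeMatrix.MISSING else int(b),
                )
                rec.samples[name].phased = True
            vf.write(rec)


# ---------------------------------------------------------------------------
# catalog table round trip

_CATALOG_FIELDS = [f.name for f in dataclasses.fields(CatalogEntry)]
_CATALOG_SORT = ("snp_chrom", "sv_id", "snp_pos", "trait")


def write_catalog(entries: list[CatalogEntry], path, format: str = "tsv") -> None:
    """Write catalog entries deterministically ordered, round-trip safe."""
    ordered = sorted(entries, key=lambda e: tuple(getattr(e, k) for k in _CATALOG_SORT))
    records = [dataclasses.asdict(e) for e in ordered]
    if format == "tsv":
        df = pd.DataFrame(records, columns=_CATALOG_FIELDS)
        # repr-format floats so the round trip is bit-exact
        for col in df.columns:
            if df[col].dtype == float:
                df[col] = df[col].map(lambda v: repr(float(v)))
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        Path(path).write_text(json.dumps(records, indent=1) + "\n")
    else:
        raise ValueError(f"unknown catalog format {format!r}")


def read_catalog(path, format: str = "tsv") -> list[CatalogEntry]:
    if format == "json":
        records = json.loads(Path(path).read_text())
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        records = df.to_dict(orient="records")
    else:
        raise ValueError(f"unknown catalog format {format!r}")
    entries = []
    types = {f.name: f.type for f in dataclasses.fields(CatalogEntry)}
    for rec in records:
        kwargs = {}
        for name in _CATALOG_FIELDS:
            val = rec[name]
            t = types[name]
            if t in ("int", int):
                val = int(val)
            elif t in ("float", float):
                val = float(val)
            else:
                val = str(val)
            kwargs[name] = val
        entries.append(CatalogEntry(**kwargs))
    return entries
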