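"""Synthetic fixtures for every pipeline stage.

The generator emulates the study conditions the pipeline was built for:
a cohort of 101 samples sequenced on two platforms, SV lengths mixing
two lognormal modes near 300 bp (Alu) and 6,000 bp (LINE), insertions
and deletions dominating the type mix, and per-caller detection noise
(missed calls, breakpoint jitter, length jitter, false positives,
genotype errors).  Haplotype columns with controlled LD are constructed
deterministically from target frequencies — counts, not samples — so LD
targets are exact up to integer rounding.

All randomness flows through one seed; per-purpose substreams are
derived by stable hashing of (seed, purpose), so every emitted file is
byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import GwasAssociation, HaplotypeMatrix, MergedSV, SVCall
from .vcf_io import write_merged_vcf


@dataclass
class CallerProfile:
    detection_prob: float = 1.0
    breakpoint_jitter_sd: float = 0.0  # bp
    length_jitter_frac: float = 0.0
    false_positive_rate: float = 0.0  # expected FP calls per sample
    genotype_error_rate: float = 0.0
    svtypes: tuple[str, ...] = ("DEL", "INS", "DUP", "INV")


def default_caller_profiles() -> dict[str, CallerProfile]:
    """Noise profiles loosely reflecting each caller's strengths.

    Long-read callers see most SV classes with tight breakpoints; the
    linked-read callers are less sensitive, read-depth callers (CNVnator,
    ERDS) only see copy-number classes, and Long Ranger contributes
    deletions only.
    """
    return {
        "pbsv": CallerProfile(0.95, 15.0, 0.02, 0.5, 0.02),
        "sniffles": CallerProfile(0.90, 30.0, 0.05, 1.0, 0.04),
        "manta": CallerProfile(0.70, 25.0, 0.05, 1.0, 0.05),
        "cnvnator": CallerProfile(0.50, 120.0, 0.10, 0.5, 0.08, ("DEL", "DUP")),
        "erds": CallerProfile(0.50, 120.0, 0.10, 0.5, 0.08, ("DEL", "DUP")),
        "longranger": CallerProfile(0.40, 60.0, 0.08, 0.5, 0.06, ("DEL",)),
    }


@dataclass
class SimConfig:
    seed: int = 0
    n_samples: int = 101
    n_truth_svs: int = 200
    chrom: str = "chr1"
    region_start: int = 1_000_000
    region_end: int = 60_000_000
    min_gap_bp: int = 5_000  # spacing so consensus clusters stay unambiguous
    # SV length mixture: lognormal modes at the Alu and LINE scales
    length_modes: tuple[float, float] = (300.0, 6000.0)
    length_mode_weights: tuple[float, float] = (0.7, 0.3)
    length_sigma: float = 0.35
    min_length: int = 60
    # type mix: insertions and deletions dominate long-read call sets
    svtype_probs: tuple[float, float, float, float] = (0.45, 0.45, 0.06, 0.04)
    naf_range: tuple[float, float] = (0.02, 0.7)
    caller_profiles: dict[str, CallerProfile] = field(
        default_factory=default_caller_profiles
    )
    ld_targets: list[tuple[float, float, float]] = field(default_factory=list)

    def rng(self, purpose: str) -> np.random.Generator:
        sub = zlib.crc32(purpose.encode()) & 0x7FFFFFFF
        return np.random.default_rng([self.seed & 0x7FFFFFFF, sub])


@dataclass
class TruthSV:
    """A ground-truth SV with phased per-sample alleles."""

    truth_id: str
    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    haplotypes: np.ndarray  # (n_samples, 2) in {0, 1}
    sample_ids: list[str]

    @property
    def naf(self) -> float:
        return float(self.haplotypes.mean())

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def genotype(self, sample_idx: int) -> str:
        a, b = self.haplotypes[sample_idx]
        return f"{a}|{b}"

    def to_merged(self) -> MergedSV:
        return MergedSV(
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            svtype=self.svtype,
            length=self.length,
            genotypes={
                s: self.genotype(i) for i, s in enumerate(self.sample_ids)
            },
        )


def simulate_truth(cfg: SimConfig) -> list[TruthSV]:
    """Draw a spaced truth SV set with Hardy-Weinberg genotypes.

    Intervals are laid down left to right with at least ``min_gap_bp``
    between events, so no two truth SVs of the same type can satisfy the
    merge predicate; density that cannot fit the region is an error.
    """
    rng = cfg.rng("truth")
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    svs: list[TruthSV] = []
    cursor = cfg.region_start
    svtypes = np.array(["DEL", "INS", "DUP", "INV"])
    for k in range(cfg.n_truth_svs):
        svtype = str(rng.choice(svtypes, p=cfg.svtype_probs))
        mode = rng.choice(2, p=cfg.length_mode_weights)
        length = int(
            np.exp(rng.normal(np.log(cfg.length_modes[mode]), cfg.length_sigma))
        )
        length = max(length, cfg.min_length)
        gap = cfg.min_gap_bp + int(rng.integers(0, cfg.min_gap_bp))
        start = cursor + gap
        span = 1 if svtype == "INS" else length
        end = start + span
        if end > cfg.region_end:
            raise ValueError(
                f"cannot place {cfg.n_truth_svs} SVs in the configured region"
            )
        cursor = end
        naf = rng.uniform(*cfg.naf_range)
        haps = (rng.random((cfg.n_samples, 2)) < naf).astype(np.int8)
        svs.append(
            TruthSV(
                truth_id=f"truth_{k:04d}",
                chrom=cfg.chrom,
                start=start,
                end=end,
                svtype=svtype,
                length=length,
                haplotypes=haps,
                sample_ids=samples,
            )
        )
    return svs


def _jittered_call(
    truth: TruthSV, sample_idx: int, caller: str, platform: str,
    profile: CallerProfile, rng: np.random.Generator,
) -> SVCall:
    jitter = lambda: int(round(rng.normal(0.0, profile.breakpoint_jitter_sd)))
    start = max(0, truth.start + jitter())
    if truth.svtype == "INS":
        end = start + 1
        length = max(
            1,
            int(round(truth.length * (1 + rng.normal(0.0, profile.length_jitter_frac))))
            if profile.length_jitter_frac
            else truth.length,
        )
    else:
        end = max(start + 1, truth.end + jitter())
        length = end - start
    a, b = truth.haplotypes[sample_idx]
    gt = f"{a}/{b}" if a <= b else f"{b}/{a}"
    if profile.genotype_error_rate and rng.random() < profile.genotype_error_rate:
        gt = "1/1" if gt == "0/1" else "0/1"
    return SVCall(
        chrom=truth.chrom,
        start=start,
        end=end,
        svtype=truth.svtype,
        length=length,
        genotype=gt,
        sample_id=truth.sample_ids[sample_idx],
        caller=caller,
        platform=platform,
        source_record_id=truth.truth_id,
    )


def simulate_caller_calls(
    truth: list[TruthSV], cfg: SimConfig
) -> tuple[list[SVCall], list[tuple[str, str, str, str]]]:
    """Per-sample, per-caller noisy calls plus a provenance manifest.

    The manifest maps each emitted call to its truth id ("FP" for false
    positives): rows of (sample, caller, source_record_id, truth_id).
    """
    from .model import PLATFORM_OF_CALLER

    calls: list[SVCall] = []
    manifest: list[tuple[str, str, str, str]] = []
    n_samples = cfg.n_samples
    for caller, profile in sorted(cfg.caller_profiles.items()):
        rng = cfg.rng(f"caller:{caller}")
        platform = PLATFORM_OF_CALLER[caller]
        for si in range(n_samples):
            sample = truth[0].sample_ids[si] if truth else f"S{si:03d}"
            for t in truth:
                if t.svtype not in profile.svtypes:
                    continue
                if not t.haplotypes[si].any():
                    continue
                if rng.random() >= profile.detection_prob:
                    continue
                call = _jittered_call(t, si, caller, platform, profile, rng)
                calls.append(call)
                rec_id = f"{call.chrom}:{call.start}-{call.end}:{call.svtype}"
                manifest.append((sample, caller, rec_id, t.truth_id))
            n_fp = rng.poisson(profile.false_positive_rate)
            for f in range(n_fp):
                start = int(rng.integers(cfg.region_start, cfg.region_end))
                length = int(rng.integers(cfg.min_length, 5 * cfg.min_length))
                svtype = str(rng.choice(np.array(profile.svtypes)))
                fp_id = f"FP_{caller}_{sample}_{f}"
                end = start + 1 if svtype == "INS" else start + length
                calls.append(
                    SVCall(
                        chrom=cfg.chrom,
                        start=start,
                        end=end,
                        svtype=svtype,
                        length=length,
                        genotype="0/1",
                        sample_id=sample,
                        caller=caller,
                        platform=platform,
                        source_record_id=fp_id,
                    )
                )
                manifest.append(
                    (sample, caller, f"{cfg.chrom}:{start}-{end}:{svtype}", "FP")
                )
    return calls, manifest


def emit_caller_vcfs(
    truth: list[TruthSV], cfg: SimConfig, outdir
) -> dict[tuple[str, str], Path]:
    """Write one VCF per (sample, caller) plus a manifest TSV.

    Returns the path map; the manifest lands at ``<outdir>/manifest.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calls, manifest = simulate_caller_calls(truth, cfg)
    by_file: dict[tuple[str, str], list[SVCall]] = {}
    for c in calls:
        by_file.setdefault((c.sample_id, c.caller), []).append(c)
    paths: dict[tuple[str, str], Path] = {}
    for (sample, caller), group in sorted(by_file.items()):
        path = outdir / f"{sample}.{caller}.vcf"
        merged_view = [
            MergedSV(
                chrom=c.chrom,
                start=c.start,
                end=c.end,
                svtype=c.svtype,
                length=c.length,
                genotypes={sample: c.genotype},
                provenance=[(sample, caller, c.platform, c.start, c.end, c.length)],
            )
            for c in group
        ]
        write_merged_vcf(merged_view, path, sample_ids=[sample])
        paths[(sample, caller)] = path
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("sample\tcaller\trecord_id\ttruth_id\n")
        for row in sorted(manifest):
            fh.write("\t".join(row) + "\n")
    return paths


def construct_haplotypes(
    p_a: float, p_b: float, d_prime_target: float, n_haplotypes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two phased allele columns realizing target frequencies and D'.

    Haplotype cell counts (n_AB, n_Ab, n_aB, n_ab) are computed from the
    target frequencies and D = D' x Dmax, then rounded to integers by
    largest remainder so they conserve ``n_haplotypes``.  The realized
    statistics are exactly recomputable from the counts — construction is
    deterministic, not sampled.  A target implying a negative cell is an
    error.
    """
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise ValueError("target frequencies must lie strictly in (0, 1)")
    if not (-1 <= d_prime_target <= 1):
        raise ValueError("d_prime_target must lie in [-1, 1]")
    if d_prime_target >= 0:
        d = d_prime_target * min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d = d_prime_target * min(p_a * p_b, (1 - p_a) * (1 - p_b))
    p_ab = p_a * p_b + d
    probs = np.array(
        [p_ab, p_a - p_ab, p_b - p_ab, 1 - p_a - p_b + p_ab], dtype=float
    )
    if (probs < -1e-12).any():
        raise ValueError("infeasible LD target: negative haplotype class")
    probs = np.clip(probs, 0.0, None)
    raw = probs * n_haplotypes
    counts = np.floor(raw).astype(int)
    shortfall = n_haplotypes - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for idx in order[:shortfall]:
        counts[idx] += 1
    n_ab_, n_a_only, n_b_only, n_none = counts
    col_a = np.concatenate(
        [
            np.ones(n_ab_ + n_a_only, dtype=np.int8),
            np.zeros(n_b_only + n_none, dtype=np.int8),
        ]
    )
    col_b = np.concatenate(
        [
            np.ones(n_ab_, dtype=np.int8),
            np.zeros(n_a_only, dtype=np.int8),
            np.ones(n_b_only, dtype=np.int8),
            np.zeros(n_none, dtype=np.int8),
        ]
    )
    return col_a, col_b


def ld_fixture(
    cfg: SimConfig,
) -> tuple[list[MergedSV], HaplotypeMatrix, list[GwasAssociation]]:
    """A paired SV/SNP haplotype matrix realizing ``cfg.ld_targets``.

    For each (p_a, p_b, d_prime) target one SV and one SNP 10 kb apart
    are constructed on ``cfg.chrom``; the matrix holds both columns and
    the association list provides a matching GWAS Catalog entry per SNP.
    """
    if cfg.n_samples * 2 <= 0:
        raise ValueError("need at least one sample")
    n_hap = 2 * cfg.n_samples
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    svs: list[MergedSV] = []
    assocs: list[GwasAssociation] = []
    variant_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    pos0 = cfg.region_start
    for k, (p_a, p_b, dp) in enumerate(cfg.ld_targets):
        col_a, col_b = construct_haplotypes(p_a, p_b, dp, n_hap)
        sv_start = pos0 + k * 100_000
        sv_end = sv_start + 500
        snp_pos = sv_end + 10_000  # 1-based
        sv = MergedSV(
            chrom=cfg.chrom,
            start=sv_start,
            end=sv_end,
            svtype="DEL",
            length=500,
            genotypes={
                s: f"{col_a[2 * i]}|{col_a[2 * i + 1]}" for i, s in enumerate(samples)
            },
        )
        svs.append(sv)
        rsid = f"rs{900000 + k}"
        variant_ids.extend([sv.sv_id, rsid])
        chroms.extend([cfg.chrom, cfg.chrom])
        positions.extend([sv_start + 1, snp_pos])
        refs.extend(["N", "A"])
        alts.extend(["<DEL>", "G"])
        rows.append(col_a.reshape(cfg.n_samples, 2))
        rows.append(col_b.reshape(cfg.n_samples, 2))
        assocs.append(
            GwasAssociation(
                rsid=rsid,
                chrom=cfg.chrom,
                pos=snp_pos,
                ref_allele="A",
                alt_allele="G",
                trait=f"trait_{k}",
                pvalue=1e-8,
                study_id=f"GCST{k:06d}",
            )
        )
    matrix = HaplotypeMatrix(
        variant_ids=variant_ids,
        sample_ids=samples,
        alleles=np.stack(rows) if rows else np.zeros((0, cfg.n_samples, 2), np.int8),
        chroms=chroms,
        positions=positions,
        refs=refs,
        alts=alts,
    )
    return svs, matrix, assocs


def emit_gwas_catalog_tsv(assocs: list[GwasAssociation], path) -> None:
    """Write associations in the catalog v1.0 dialect (plus REF/ALT columns)."""
    cols = [
        "DISEASE/TRAIT",
        "CHR_ID",
        "CHR_POS",
        "SNPS",
        "STRONGEST SNP-RISK ALLELE",
        "P-VALUE",
        "STUDY ACCESSION",
        "REF_ALLELE",
        "ALT_ALLELE",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for a in assocs:
            chrom = a.chrom.removeprefix("chr")
            fh.write(
                "\t".join(
                    [
                        a.trait,
                        chrom,
                        str(a.pos),
                        a.rsid,
                        f"{a.rsid}-{a.alt_allele or '?'}",
                        f"{a.pvalue:G}",
                        a.study_id,
                        a.ref_allele,
                        a.alt_allele,
                    ]
                )
                + "\n"
            )
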