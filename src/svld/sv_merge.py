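"""Consensus merging of multi-caller, multi-platform SV calls.

The merge proceeds in three steps per sample — within the PacBio CLR
callers (pbsv anchored, Sniffles supporting), within the linked-read
callers (Manta anchored; CNVnator, ERDS, Long Ranger supporting, Long
Ranger restricted to deletions) — then across the two platforms, with
PacBio boundaries and genotypes taking precedence where both platforms
called the event.  Finally calls are consolidated across samples into one
catalog, clusters with no constituent above the SV size floor are dropped,
and rare events seen in fewer than the minimum number of carriers are
removed.

Matching uses a 50% reciprocal-overlap rule for deletions, duplications
and inversions; insertions match when their breakpoints lie within
1,000 bp and their lengths are within 50% of one another.  Consensus
boundaries are the arithmetic mean of the constituent breakpoints.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .model import (
    ALL_CALLERS,
    FeatureInterval,
    MergedSV,
    SVCall,
    is_carrier,
    parse_genotype,
)

logger = logging.getLogger(__name__)


@dataclass
class MergeConfig:
    reciprocal_overlap_min: float = 0.5
    ins_breakpoint_max_dist: int = 1000  # inclusive bound
    ins_size_ratio_min: float = 0.5
    min_constituent_len: int = 50  # strict >
    min_carriers: int = 3
    anchor_order_pacbio: tuple[str, ...] = ("pbsv", "sniffles")
    anchor_order_tenx: tuple[str, ...] = ("manta", "cnvnator", "erds", "longranger")
    longranger_types: tuple[str, ...] = ("DEL",)

    def __post_init__(self) -> None:
        for frac in (self.reciprocal_overlap_min, self.ins_size_ratio_min):
            if not (0 < frac <= 1):
                raise ValueError("overlap/size fractions must lie in (0, 1]")
        if self.min_carriers < 1:
            raise ValueError("min_carriers must be >= 1")


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|) for two half-open intervals; 0 if disjoint."""
    if a[1] <= a[0] or b[1] <= b[0]:
        raise ValueError("reciprocal overlap is undefined for empty intervals")
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def sv_match(a, b, cfg: MergeConfig) -> bool:
    """Type-specific merge predicate over anything with interval attributes.

    Accepts SVCall, MergedSV or MergeCluster (duck-typed on chrom, svtype,
    start, end, length).
    """
    if a.svtype != b.svtype or a.chrom != b.chrom:
        return False
    if a.svtype == "INS":
        if abs(a.start - b.start) > cfg.ins_breakpoint_max_dist:
            return False
        lo, hi = sorted((a.length, b.length))
        if hi == 0:
            return False
        return lo / hi >= cfg.ins_size_ratio_min
    return reciprocal_overlap((a.start, a.end), (b.start, b.end)) >= cfg.reciprocal_overlap_min


def _match_score(call, rep, cfg: MergeConfig) -> tuple:
    """Sortable goodness of a candidate match; larger is better.

    DEL/DUP/INV rank by reciprocal overlap; INS by breakpoint proximity
    then by size-ratio closeness.  Remaining ties go to the leftmost
    representative.
    """
    if call.svtype == "INS":
        lo, hi = sorted((call.length, rep.length))
        ratio = lo / hi if hi else 0.0
        return (-abs(call.start - rep.start), ratio, -rep.start)
    ro = reciprocal_overlap((call.start, call.end), (rep.start, rep.end))
    return (ro, 0.0, -rep.start)


@dataclass
class MergeCluster:
    """A set of mutually matching calls with an averaged representative."""

    members: list[SVCall]
    anchor_order: tuple[str, ...]

    # representative (duck-typed like an interval-bearing call)
    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def svtype(self) -> str:
        return self.members[0].svtype

    @property
    def start(self) -> int:
        return _round_half_up(sum(m.start for m in self.members) / len(self.members))

    @property
    def end(self) -> int:
        if self.svtype == "INS":
            return self.start + 1
        return _round_half_up(sum(m.end for m in self.members) / len(self.members))

    @property
    def length(self) -> int:
        if self.svtype == "INS":
            return _round_half_up(sum(m.length for m in self.members) / len(self.members))
        return self.end - self.start

    @property
    def anchor(self) -> SVCall:
        """Member whose caller ranks first in the configured anchor order."""
        rank = {c: i for i, c in enumerate(self.anchor_order)}
        return min(
            self.members,
            key=lambda m: (rank.get(m.caller, len(rank)), m.start, m.end),
        )

    @property
    def genotype(self) -> str:
        return self.anchor.genotype

    @property
    def sample_id(self) -> str:
        return self.members[0].sample_id

    def callers(self) -> set[str]:
        return {m.caller for m in self.members}


def _call_sort_key(c: SVCall) -> tuple:
    return (c.chrom, c.start, c.end, c.svtype, c.length)


def dedupe_repeat_calls(
    calls: list[SVCall],
    repeats: list[FeatureInterval],
    cfg: MergeConfig | None = None,
) -> list[SVCall]:
    """Collapse same-type calls with similar breakpoints inside one repeat.

    Calls of equal type that mutually satisfy the merge predicate and each
    overlap the same repeat element are redundant detections of one
    polymorphism; only the longest (ties: leftmost) is kept.  Calls outside
    repeats, or not matching each other, are untouched.
    """
    cfg = cfg or MergeConfig()
    if not repeats:
        return list(calls)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, feat in enumerate(repeats):
        trees[feat.chrom].addi(feat.start, feat.end, i)

    ordered = sorted(calls, key=_call_sort_key)
    parent = list(range(len(ordered)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    repeat_hits: list[set[int]] = []
    for c in ordered:
        qend = max(c.end, c.start + 1)  # INS anchor still probes the tree
        hits = {iv.data for iv in trees[c.chrom].overlap(c.start, qend)}
        repeat_hits.append(hits)

    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            if a.svtype != b.svtype or a.chrom != b.chrom:
                continue
            if not (repeat_hits[i] & repeat_hits[j]):
                continue
            if sv_match(a, b, cfg):
                union(i, j)

    by_root: dict[int, list[int]] = defaultdict(list)
    for i in range(len(ordered)):
        by_root[find(i)].append(i)

    kept: list[SVCall] = []
    n_dropped = 0
    for idxs in by_root.values():
        best = max(idxs, key=lambda i: (ordered[i].length, -ordered[i].start))
        kept.append(ordered[best])
        n_dropped += len(idxs) - 1
    if n_dropped:
        logger.info("dedupe_repeat_calls: dropped %d redundant repeat calls", n_dropped)
    return sorted(kept, key=_call_sort_key)


def merge_within_platform(
    calls_by_caller: dict[str, list[SVCall]],
    anchor_order: tuple[str, ...],
    cfg: MergeConfig,
) -> list[MergeCluster]:
    """Anchor-and-tag merge of one sample's calls within one platform.

    The anchor caller's calls seed clusters; each subsequent caller's
    calls, in the configured order, attach one-to-one to the best-matching
    existing cluster or seed a new cluster (unique calls are retained).
    """
    unknown = set(calls_by_caller) - set(anchor_order)
    if unknown:
        raise ValueError(f"unknown caller(s) {sorted(unknown)}; expected {anchor_order}")
    clusters: list[MergeCluster] = [
        MergeCluster([c], anchor_order)
        for c in sorted(calls_by_caller.get(anchor_order[0], []), key=_call_sort_key)
    ]
    for caller in anchor_order[1:]:
        tagged: set[int] = set()  # one tag per cluster per supporting caller
        for call in sorted(calls_by_caller.get(caller, []), key=_call_sort_key):
            best_idx = None
            best_score = None
            for idx, cluster in enumerate(clusters):
                if idx in tagged:
                    continue
                if not sv_match(call, cluster, cfg):
                    continue
                score = _match_score(call, cluster, cfg)
                if best_score is None or score > best_score:
                    best_idx, best_score = idx, score
            if best_idx is None:
                clusters.append(MergeCluster([call], anchor_order))
            else:
                clusters[best_idx].members.append(call)
                tagged.add(best_idx)
    return sorted(clusters, key=lambda cl: (cl.chrom, cl.start, cl.end, cl.svtype))


def _cluster_to_merged(cluster: MergeCluster) -> MergedSV:
    return MergedSV(
        chrom=cluster.chrom,
        start=cluster.start,
        end=cluster.end,
        svtype=cluster.svtype,
        length=cluster.length,
        genotypes={cluster.sample_id: cluster.genotype},
        provenance=[
            (m.sample_id, m.caller, m.platform, m.start, m.end, m.length)
            for m in cluster.members
        ],
    )


def merge_cross_platform(
    pacbio: list[MergeCluster],
    tenx: list[MergeCluster],
    cfg: MergeConfig,
) -> list[MergedSV]:
    """Merge one sample's platform-level clusters across platforms.

    Matched pairs emit one call carrying the PacBio CLR boundaries and
    genotype; unmatched clusters on either side pass through unchanged.
    """
    used_tenx: set[int] = set()
    out: list[MergedSV] = []
    tenx_sorted = sorted(
        enumerate(tenx), key=lambda t: (t[1].chrom, t[1].start, t[1].end)
    )
    for pb in sorted(pacbio, key=lambda cl: (cl.chrom, cl.start, cl.end)):
        best = None
        best_score = None
        for idx, tx in tenx_sorted:
            if idx in used_tenx or not sv_match(pb, tx, cfg):
                continue
            score = _match_score(pb, tx, cfg)
            if best_score is None or score > best_score:
                best, best_score = idx, score
        merged = _cluster_to_merged(pb)
        if best is not None:
            used_tenx.add(best)
            merged.provenance.extend(
                (m.sample_id, m.caller, m.platform, m.start, m.end, m.length)
                for m in tenx[best].members
            )
        out.append(merged)
    for idx, tx in tenx_sorted:
        if idx not in used_tenx:
            out.append(_cluster_to_merged(tx))
    return sorted(out, key=lambda sv: (sv.chrom, sv.start, sv.end, sv.svtype))


@dataclass
class _SampleCluster:
    members: list[MergedSV] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def svtype(self) -> str:
        return self.members[0].svtype

    @property
    def start(self) -> int:
        return _round_half_up(sum(m.start for m in self.members) / len(self.members))

    @property
    def end(self) -> int:
        if self.svtype == "INS":
            return self.start + 1
        return _round_half_up(sum(m.end for m in self.members) / len(self.members))

    @property
    def length(self) -> int:
        if self.svtype == "INS":
            return _round_half_up(sum(m.length for m in self.members) / len(self.members))
        return self.end - self.start


def consolidate_across_samples(
    per_sample: dict[str, list[MergedSV]],
    cfg: MergeConfig,
) -> list[MergedSV]:
    """Greedy single-linkage consolidation of per-sample calls.

    Calls are scanned in (chrom, start) order and attached to the cluster
    whose running representative (mean of member breakpoints) they match
    best, or seed a new cluster.  Clusters whose members are all at or
    below the size floor are dropped; output calls carry a genotype for
    every sample (absent samples are homozygous reference).
    """
    all_samples = sorted(per_sample)
    flat: list[MergedSV] = [sv for calls in per_sample.values() for sv in calls]
    flat.sort(key=lambda sv: (sv.chrom, sv.start, sv.end, sv.svtype))

    clusters: list[_SampleCluster] = []
    by_key: dict[tuple[str, str], list[int]] = defaultdict(list)
    for sv in flat:
        best_idx = None
        best_score = None
        for idx in by_key[(sv.chrom, sv.svtype)]:
            rep = clusters[idx]
            if not sv_match(sv, rep, cfg):
                continue
            score = _match_score(sv, rep, cfg)
            if best_score is None or score > best_score:
                best_idx, best_score = idx, score
        if best_idx is None:
            clusters.append(_SampleCluster([sv]))
            by_key[(sv.chrom, sv.svtype)].append(len(clusters) - 1)
        else:
            clusters[best_idx].members.append(sv)

    out: list[MergedSV] = []
    n_dropped = 0
    for cl in clusters:
        max_len = max(m.length for m in cl.members)
        if max_len <= cfg.min_constituent_len:
            n_dropped += 1
            continue
        genotypes = {s: "0/0" for s in all_samples}
        for m in sorted(cl.members, key=lambda sv: (sv.chrom, sv.start, sv.end)):
            for sample, gt in m.genotypes.items():
                # prefer a carrier genotype when one sample contributed twice
                if genotypes.get(sample) in ("0/0", None) or not is_carrier(genotypes[sample]):
                    genotypes[sample] = gt
        provenance = [p for m in cl.members for p in m.provenance]
        out.append(
            MergedSV(
                chrom=cl.chrom,
                start=cl.start,
                end=cl.end,
                svtype=cl.svtype,
                length=cl.length,
                genotypes=genotypes,
                provenance=provenance,
            )
        )
    if n_dropped:
        logger.info(
            "consolidate_across_samples: dropped %d clusters with no member > %d bp",
            n_dropped,
            cfg.min_constituent_len,
        )
    return sorted(out, key=lambda sv: (sv.chrom, sv.start, sv.end, sv.svtype))


def filter_by_carriers(svs: list[MergedSV], cfg: MergeConfig) -> list[MergedSV]:
    """Drop SVs seen in fewer than ``cfg.min_carriers`` participants."""
    kept = [sv for sv in svs if sv.carrier_count >= cfg.min_carriers]
    removed = len(svs) - len(kept)
    if removed:
        logger.info("filter_by_carriers: removed %d SVs with < %d carriers", removed, cfg.min_carriers)
    return kept


def merge_pipeline(
    calls: list[SVCall],
    repeats: list[FeatureInterval] | None = None,
    cfg: MergeConfig | None = None,
    apply_carrier_filter: bool = True,
) -> list[MergedSV]:
    """Run the full merge: per-sample platform merges, cross-platform
    merge, cross-sample consolidation, and the carrier filter.

    ``calls`` may mix samples, callers and platforms; pbsv calls are
    first deduplicated against the repeat track, and Long Ranger calls
    are restricted to the configured types.
    """
    cfg = cfg or MergeConfig()
    repeats = repeats or []
    by_sample: dict[str, dict[str, list[SVCall]]] = defaultdict(lambda: defaultdict(list))
    for c in calls:
        if c.caller not in ALL_CALLERS:
            raise ValueError(f"unknown caller {c.caller!r}")
        if c.caller == "longranger" and c.svtype not in cfg.longranger_types:
            continue
        by_sample[c.sample_id][c.caller].append(c)

    per_sample: dict[str, list[MergedSV]] = {}
    for sample, by_caller in by_sample.items():
        if "pbsv" in by_caller:
            by_caller["pbsv"] = dedupe_repeat_calls(by_caller["pbsv"], repeats, cfg)
        pb_input = {c: v for c, v in by_caller.items() if c in cfg.anchor_order_pacbio}
        tx_input = {c: v for c, v in by_caller.items() if c in cfg.anchor_order_tenx}
        pb = merge_within_platform(pb_input, cfg.anchor_order_pacbio, cfg)
        tx = merge_within_platform(tx_input, cfg.anchor_order_tenx, cfg)
        per_sample[sample] = merge_cross_platform(pb, tx, cfg)

    consolidated = consolidate_across_samples(per_sample, cfg)
    if apply_carrier_filter:
        consolidated = filter_by_carriers(consolidated, cfg)
    return consolidated
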