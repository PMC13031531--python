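"""Consensus-merge predicates, anchor/tag clustering and filters."""

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svld.model import FeatureInterval
from svld.sv_merge import (
    MergeConfig,
    consolidate_across_samples,
    dedupe_repeat_calls,
    filter_by_carriers,
    merge_cross_platform,
    merge_pipeline,
    merge_within_platform,
    reciprocal_overlap,
    sv_match,
)

from conftest import make_call, make_merged

CFG = MergeConfig()


class TestReciprocalOverlap:
    def test_identity_is_one(self):
        assert reciprocal_overlap((100, 200), (100, 200)) == 1.0

    def test_disjoint_is_zero(self):
        assert reciprocal_overlap((100, 200), (300, 400)) == 0.0

    def test_half_overlap(self):
        assert reciprocal_overlap((100, 200), (150, 250)) == pytest.approx(0.5)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            reciprocal_overlap((100, 100), (100, 200))

    @given(
        a0=st.integers(0, 10_000),
        alen=st.integers(1, 5_000),
        b0=st.integers(0, 10_000),
        blen=st.integers(1, 5_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_bounded(self, a0, alen, b0, blen):
        a, b = (a0, a0 + alen), (b0, b0 + blen)
        ro = reciprocal_overlap(a, b)
        assert 0.0 <= ro <= 1.0
        assert ro == reciprocal_overlap(b, a)


class TestSvMatch:
    def test_deletions_above_threshold(self):
        a = make_call(start=0, end=1000)
        b = make_call(start=400, end=1400, caller="sniffles")
        assert sv_match(a, b, CFG)  # overlap 600 / 1000 = 0.6

    def test_insertion_distance_boundary_inclusive(self):
        a = make_call(start=10_000, svtype="INS", length=300)
        b = make_call(start=11_000, svtype="INS", length=300)
        assert sv_match(a, b, CFG)
        c = make_call(start=11_001, svtype="INS", length=300)
        assert not sv_match(a, c, CFG)

    def test_insertion_size_ratio(self):
        a = make_call(start=10_000, svtype="INS", length=300)
        b = make_call(start=10_100, svtype="INS", length=100)
        assert not sv_match(a, b, CFG)  # ratio 1/3 < 0.5
        c = make_call(start=10_100, svtype="INS", length=150)
        assert sv_match(a, c, CFG)  # ratio 0.5 at the boundary

    def test_type_and_chrom_mismatch(self):
        a = make_call(start=0, end=1000)
        assert not sv_match(a, make_call(start=0, end=1000, svtype="DUP"), CFG)
        assert not sv_match(a, make_call(chrom="chr2", start=0, end=1000), CFG)

    @given(
        s1=st.integers(0, 50_000),
        l1=st.integers(51, 5_000),
        s2=st.integers(0, 50_000),
        l2=st.integers(51, 5_000),
        svtype=st.sampled_from(["DEL", "INS", "DUP", "INV"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetry(self, s1, l1, s2, l2, svtype):
        a = make_call(start=s1, end=s1 + l1, svtype=svtype, length=l1)
        b = make_call(start=s2, end=s2 + l2, svtype=svtype, length=l2)
        assert sv_match(a, b, CFG) == sv_match(b, a, CFG)


class TestDedupeRepeatCalls:
    def test_matching_pair_in_repeat_collapses(self):
        repeat = [FeatureInterval("chr1", 900, 2500, "repeat", "AluY")]
        calls = [
            make_call(start=1000, end=2000),
            make_call(start=1100, end=2100),
        ]
        kept = dedupe_repeat_calls(calls, repeat)
        assert len(kept) == 1
        assert (kept[0].start, kept[0].end) == (1000, 2000)  # equal length, leftmost

    def test_longest_representative_kept(self):
        repeat = [FeatureInterval("chr1", 0, 5000, "repeat", "L1")]
        calls = [
            make_call(start=1000, end=2000),
            make_call(start=950, end=2150),
        ]
        (kept,) = dedupe_repeat_calls(calls, repeat)
        assert (kept.start, kept.end) == (950, 2150)

    def test_no_repeat_overlap_keeps_both(self):
        repeat = [FeatureInterval("chr1", 50_000, 60_000, "repeat", "L1")]
        calls = [make_call(start=1000, end=2000), make_call(start=1100, end=2100)]
        assert len(dedupe_repeat_calls(calls, repeat)) == 2

    def test_empty_track_is_identity(self):
        calls = [make_call(start=1000, end=2000), make_call(start=1100, end=2100)]
        assert dedupe_repeat_calls(calls, []) == calls


class TestMergeWithinPlatform:
    def test_supporting_call_tags_anchor(self):
        pbsv = [make_call(start=1000, end=2000, caller="pbsv", genotype="1/1")]
        sniffles = [make_call(start=1100, end=2100, caller="sniffles", genotype="0/1")]
        (cluster,) = merge_within_platform(
            {"pbsv": pbsv, "sniffles": sniffles}, CFG.anchor_order_pacbio, CFG
        )
        assert (cluster.start, cluster.end) == (1050, 2050)  # averaged breakpoints
        assert cluster.genotype == "1/1"  # anchor caller's genotype
        assert cluster.callers() == {"pbsv", "sniffles"}

    def test_unique_supporting_call_retained_as_singleton(self):
        sniffles = [make_call(start=9_000_000, svtype="INS", caller="sniffles")]
        clusters = merge_within_platform(
            {"sniffles": sniffles}, CFG.anchor_order_pacbio, CFG
        )
        assert len(clusters) == 1 and clusters[0].callers() == {"sniffles"}

    def test_no_supporting_callers_yields_anchor_calls(self):
        pbsv = [make_call(start=1000, end=2000), make_call(start=50_000, end=51_000)]
        clusters = merge_within_platform({"pbsv": pbsv}, CFG.anchor_order_pacbio, CFG)
        assert [(c.start, c.end) for c in clusters] == [(1000, 2000), (50_000, 51_000)]

    def test_supporting_call_attaches_to_best_cluster(self):
        pbsv = [
            make_call(start=1000, end=2000),
            make_call(start=1400, end=2400),
        ]
        sniffles = [make_call(start=1350, end=2350, caller="sniffles")]
        clusters = merge_within_platform(
            {"pbsv": pbsv, "sniffles": sniffles}, CFG.anchor_order_pacbio, CFG
        )
        assert len(clusters) == 2
        tagged = [c for c in clusters if "sniffles" in c.callers()]
        assert len(tagged) == 1
        # RO with [1400,2400) is 0.95 vs 0.65 with [1000,2000)
        assert 1400 in [m.start for m in tagged[0].members]

    def test_unknown_caller_fatal(self):
        with pytest.raises(ValueError, match="unknown caller"):
            merge_within_platform(
                {"mystery": [make_call()]}, CFG.anchor_order_pacbio, CFG
            )


class TestMergeCrossPlatform:
    def test_pacbio_boundaries_take_precedence(self):
        pb = merge_within_platform(
            {"pbsv": [make_call(start=1050, end=2050, genotype="0/1")]},
            CFG.anchor_order_pacbio,
            CFG,
        )
        tx = merge_within_platform(
            {"manta": [make_call(start=1000, end=2000, caller="manta", genotype="1/1")]},
            CFG.anchor_order_tenx,
            CFG,
        )
        (sv,) = merge_cross_platform(pb, tx, CFG)
        assert (sv.start, sv.end) == (1050, 2050)
        assert sv.genotypes == {"S000": "0/1"}
        assert {p[2] for p in sv.provenance} == {"pacbio_clr", "tenx_linked"}

    def test_tenx_only_cluster_passes_through(self):
        tx = merge_within_platform(
            {"manta": [make_call(start=5000, end=9000, svtype="DUP", caller="manta")]},
            CFG.anchor_order_tenx,
            CFG,
        )
        (sv,) = merge_cross_platform([], tx, CFG)
        assert (sv.start, sv.end, sv.svtype) == (5000, 9000, "DUP")

    def test_empty_pacbio_equals_tenx(self):
        tx = merge_within_platform(
            {"manta": [make_call(start=1, end=500, caller="manta")]},
            CFG.anchor_order_tenx,
            CFG,
        )
        out = merge_cross_platform([], tx, CFG)
        assert [(s.start, s.end) for s in out] == [(1, 500)]


class TestConsolidateAcrossSamples:
    def test_shared_deletion_counts_all_carriers(self):
        per_sample = {
            f"S{i}": [make_merged(start=1000, end=2000, genotypes={f"S{i}": "0/1"})]
            for i in range(5)
        }
        (sv,) = consolidate_across_samples(per_sample, CFG)
        assert sv.carrier_count == 5
        assert sv.genotypes["S0"] == "0/1"

    def test_short_cluster_dropped(self):
        per_sample = {
            "A": [make_merged(start=1000, end=1040, genotypes={"A": "0/1"})],
            "B": [make_merged(start=1001, end=1041, genotypes={"B": "0/1"})],
        }
        assert consolidate_across_samples(per_sample, CFG) == []

    def test_boundary_length_exactly_50_dropped(self):
        per_sample = {"A": [make_merged(start=0, end=50, genotypes={"A": "0/1"})]}
        assert consolidate_across_samples(per_sample, CFG) == []
        per_sample = {"A": [make_merged(start=0, end=51, genotypes={"A": "0/1"})]}
        assert len(consolidate_across_samples(per_sample, CFG)) == 1

    def test_chain_cluster_uses_mean_breakpoints(self):
        per_sample = {
            "A": [make_merged(start=0, end=1000, genotypes={"A": "0/1"})],
            "B": [make_merged(start=300, end=1300, genotypes={"B": "0/1"})],
            "C": [make_merged(start=450, end=1450, genotypes={"C": "1/1"})],
        }
        (sv,) = consolidate_across_samples(per_sample, CFG)
        assert (sv.start, sv.end) == (250, 1250)
        assert sv.genotypes == {"A": "0/1", "B": "0/1", "C": "1/1"}
        assert sv.naf == pytest.approx(4 / 6)

    def test_absent_samples_homref(self):
        per_sample = {
            "A": [make_merged(start=1000, end=2000, genotypes={"A": "0/1"})],
            "B": [],
        }
        (sv,) = consolidate_across_samples(per_sample, CFG)
        assert sv.genotypes["B"] == "0/0"


class TestFilterByCarriers:
    def test_boundary_three_carriers_survives(self):
        gts = {"A": "0/1", "B": "0/1", "C": "1/1", "D": "0/0"}
        sv3 = make_merged(genotypes=gts)
        sv2 = make_merged(start=90_000, end=91_000, genotypes={"A": "0/1", "B": "0/1"})
        kept = filter_by_carriers([sv3, sv2], CFG)
        assert kept == [sv3]

    def test_hand_counted_fixture(self):
        svs = []
        for i in range(10):
            n_car = 2 if i < 4 else 3 + i % 3
            gts = {f"S{j}": ("0/1" if j < n_car else "0/0") for j in range(8)}
            svs.append(make_merged(start=10_000 * (i + 1), end=10_000 * (i + 1) + 500, genotypes=gts))
        assert len(filter_by_carriers(svs, CFG)) == 6

    def test_never_alters_intervals(self):
        svs = [make_merged(genotypes={c: "0/1" for c in "ABCDE"})]
        (kept,) = filter_by_carriers(svs, CFG)
        assert (kept.start, kept.end, kept.carrier_count) == (1000, 2000, 5)


def _brute_force_components(calls, cfg):
    """Oracle: full match graph, connected components via networkx."""
    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    for i, j in itertools.combinations(range(len(calls)), 2):
        if sv_match(calls[i], calls[j], cfg):
            g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    cliques = all(
        all(g.has_edge(i, j) for i, j in itertools.combinations(c, 2))
        for c in comps
        if len(c) > 1
    )
    return comps, cliques


class TestGreedyVsBruteForceOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_clique_components_match_greedy_clusters(self, seed):
        """On fixtures whose match graph is a union of cliques, greedy
        single-linkage consolidation must equal the component oracle."""
        import numpy as np

        rng = np.random.default_rng(seed)
        calls = []
        pos = 1000
        for k in range(rng.integers(10, 50)):
            pos += int(rng.integers(3000, 9000))
            n_members = int(rng.integers(1, 4))
            base_len = int(rng.integers(100, 2000))
            svtype = str(rng.choice(["DEL", "DUP", "INV", "INS"]))
            for m in range(n_members):
                jitter = int(rng.integers(0, max(1, base_len // 20)))
                length = base_len + int(rng.integers(0, max(1, base_len // 20)))
                calls.append(
                    make_merged(
                        start=pos + jitter,
                        end=pos + jitter + length,
                        svtype=svtype,
                        length=length,
                        genotypes={f"S{m}": "0/1"},
                    )
                )
        comps, cliques = _brute_force_components(calls, CFG)
        if not cliques:
            pytest.skip("non-clique match graph; oracle not applicable")
        per_sample = {}
        for i, c in enumerate(calls):
            per_sample.setdefault(f"S{i % 3}", []).append(c)
        merged = consolidate_across_samples(per_sample, CFG)
        kept_comps = [
            c
            for c in comps
            if max(calls[i].length for i in c) > CFG.min_constituent_len
        ]
        assert len(merged) == len(kept_comps)

    def test_merge_pipeline_deterministic(self):
        from svld.synthetic import SimConfig, simulate_caller_calls, simulate_truth

        cfg = SimConfig(seed=11, n_samples=8, n_truth_svs=25)
        truth = simulate_truth(cfg)
        calls, _ = simulate_caller_calls(truth, cfg)
        a = merge_pipeline(list(calls), cfg=MergeConfig(min_carriers=1))
        b = merge_pipeline(list(reversed(calls)), cfg=MergeConfig(min_carriers=1))
        assert [(s.sv_id, sorted(s.genotypes.items())) for s in a] == [
            (s.sv_id, sorted(s.genotypes.items())) for s in b
        ]

    def test_cluster_members_pairwise_match_representative(self):
        from svld.synthetic import SimConfig, simulate_caller_calls, simulate_truth

        cfg = SimConfig(seed=13, n_samples=6, n_truth_svs=20)
        truth = simulate_truth(cfg)
        calls, _ = simulate_caller_calls(truth, cfg)
        merged = merge_pipeline(calls, cfg=MergeConfig(min_carriers=1))
        for sv in merged:
            for (_, _, _, start, end, length) in sv.provenance:
                member = make_merged(
                    start=start,
                    end=end if sv.svtype != "INS" else start + 1,
                    svtype=sv.svtype,
                    length=length,
                )
                assert sv_match(member, sv, CFG)
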