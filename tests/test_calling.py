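"""Discordant-pair classification, clustering, refinement and selection."""

import numpy as np
import pytest

import ctdna_monitor as cm
from ctdna_monitor.align import AlignedBlock, ReadAlignment
from ctdna_monitor.svcalls import (
    JunctionSide,
    SupportFragment,
    classify_pair,
    cluster_discordant,
    filter_germline,
    select_candidates,
)
from conftest import canonical_truth_sides


def _pair(chrom1, start1, strand1, chrom2, start2, strand2, length=100, fid="f"):
    a1 = ReadAlignment(fid, 1, "aligned", [AlignedBlock(chrom1, start1, start1 + length, strand1, 0, length)])
    a2 = ReadAlignment(fid, 2, "aligned", [AlignedBlock(chrom2, start2, start2 + length, strand2, 0, length)])
    return a1, a2


class TestClassifyPair:
    def test_convergent_in_window_concordant(self):
        a1, a2 = _pair("chr1", 10_000, "+", "chr1", 10_300, "-")
        assert classify_pair(a1, a2, 500, 50) == "concordant"

    def test_different_chromosomes_inter_chromosomal(self):
        a1, a2 = _pair("chr1", 10_000, "+", "chr2", 10_300, "-")
        assert classify_pair(a1, a2, 500, 50) == "inter_chromosomal"

    def test_long_span_deletion_like(self):
        a1, a2 = _pair("chr1", 10_000, "+", "chr1", 60_000, "-")
        assert classify_pair(a1, a2, 500, 50) == "deletion_like"

    def test_same_strand_inversion_like(self):
        a1, a2 = _pair("chr1", 10_000, "+", "chr1", 10_300, "+")
        assert classify_pair(a1, a2, 500, 50) == "inversion_like"

    def test_unaligned_mate_raises(self):
        a1, _ = _pair("chr1", 0, "+", "chr1", 300, "-")
        with pytest.raises(ValueError, match="aligned"):
            classify_pair(a1, ReadAlignment("f", 2, "unaligned"), 500, 50)


def _frag(pos1, pos2, fid="f", exact=False, d1="left", d2="right", c1="chr1", c2="chr2"):
    return SupportFragment(
        fid, JunctionSide(c1, pos1, d1), JunctionSide(c2, pos2, d2), exact,
        "inter_chromosomal" if c1 != c2 else "deletion_like",
    )


class TestClusterDiscordant:
    def test_fragments_around_one_junction_form_one_cluster(self):
        frags = [_frag(50_000 - 10 * i, 30_000 + 7 * i, fid=f"f{i}") for i in range(10)]
        calls = cluster_discordant(frags, window=500)
        assert len(calls) == 1
        assert calls[0].n_supporting_fragments == 10

    def test_single_fragment_below_support_threshold(self):
        assert cluster_discordant([_frag(50_000, 30_000)], window=500) == []

    def test_empty_input_empty_output(self):
        assert cluster_discordant([], window=500) == []

    def test_distant_junctions_not_merged(self):
        frags = [_frag(50_000, 30_000, "a"), _frag(50_010, 30_020, "b"),
                 _frag(10_000, 42_000, "c"), _frag(10_030, 42_010, "d")]
        calls = cluster_discordant(frags, window=500)
        assert len(calls) == 2
        assert sorted(c.n_supporting_fragments for c in calls) == [2, 2]

    def test_innermost_positions_reported(self):
        frags = [_frag(49_900, 30_100, "a"), _frag(49_950, 30_050, "b")]
        (call,) = cluster_discordant(frags, window=500)
        assert (call.pos1, call.pos2) == (49_950, 30_050)  # max for left, min for right


class TestPlantedTruthRecovery:
    def test_all_planted_junctions_recovered_at_base_precision(
        self, toy_genome, planted, tumor_reads, normal_reads
    ):
        events, donor = planted
        result = cm.call_rearrangements(tumor_reads, toy_genome, normal_reads=normal_reads)
        called = {(c.chrom1, c.pos1, c.dir1, c.chrom2, c.pos2, c.dir2) for c in result.calls}
        for junction in donor.junctions:
            s1, s2 = canonical_truth_sides(junction)
            assert s1 + s2 in called
        assert all(c.n_supporting_fragments >= 2 for c in result.calls)

    def test_fusion_sequences_match_donor(self, planted, toy_genome, tumor_reads):
        _, donor = planted
        result = cm.call_rearrangements(tumor_reads, toy_genome)
        blob = "#".join(donor.genome.chromosomes.values())
        exact = [c for c in result.calls if c.exact]
        assert exact, "expected split-read-refined calls"
        for c in exact:
            assert c.fusion_sequence is not None
            # either orientation names the same junction
            assert c.fusion_sequence in blob or cm.revcomp(c.fusion_sequence) in blob

    def test_no_calls_on_unrearranged_genome(self, toy_genome, normal_reads):
        result = cm.call_rearrangements(normal_reads, toy_genome)
        assert result.calls == []

    def test_svtype_labels_match_planted_types(self, planted, toy_genome, tumor_reads, normal_reads):
        events, donor = planted
        result = cm.call_rearrangements(tumor_reads, toy_genome, normal_reads=normal_reads)
        label = {"translocation": "t", "deletion": "del", "inversion": "inv"}
        by_sides = {
            canonical_truth_sides(j): label[j.svtype] for j in donor.junctions
        }
        for c in result.calls:
            sides = ((c.chrom1, c.pos1, c.dir1), (c.chrom2, c.pos2, c.dir2))
            assert c.svtype == by_sides[sides]

    def test_support_does_not_drop_with_more_coverage(self, toy_genome, planted):
        """Doubling coverage should not reduce a true cluster's support."""
        _, donor = planted
        totals = []
        for cov in (5.0, 10.0):
            sup = 0
            for seed in (101, 102, 103):
                reads = cm.simulate_read_pairs(donor.genome, cov, 100, 500.0, seed=seed)
                res = cm.call_rearrangements(reads, toy_genome)
                sup += sum(c.n_supporting_fragments for c in res.calls)
            totals.append(sup / 3)
        assert totals[1] > totals[0]


class TestGermlineFilter:
    def test_call_present_in_normal_removed(self):
        frags = [_frag(50_000, 30_000, "a"), _frag(50_010, 30_020, "b")]
        (call,) = cluster_discordant(frags, window=500)
        somatic, removed = filter_germline([call], [_frag(50_005, 30_010, "n")], window=500)
        assert somatic == [] and removed == 1

    def test_tumor_only_call_retained(self):
        frags = [_frag(50_000, 30_000, "a"), _frag(50_010, 30_020, "b")]
        (call,) = cluster_discordant(frags, window=500)
        somatic, removed = filter_germline([call], [_frag(10_000, 5_000, "n")], window=500)
        assert somatic == [call] and removed == 0

    def test_empty_call_set(self):
        assert filter_germline([], [], window=500) == ([], 0)

    def test_idempotence(self):
        frags = [_frag(50_000, 30_000, "a"), _frag(50_010, 30_020, "b")]
        calls = cluster_discordant(frags, window=500)
        normal = [_frag(10_000, 5_000, "n")]
        once, _ = filter_germline(calls, normal, window=500)
        twice, _ = filter_germline(once, normal, window=500)
        assert once == twice

    def test_missing_normal_flags_passthrough(self):
        frags = [_frag(50_000, 30_000, "a"), _frag(50_010, 30_020, "b")]
        calls = cluster_discordant(frags, window=500)
        out, removed = filter_germline(calls, None)
        assert removed == 0 and all("no_normal_filter" in c.flags for c in out)


def _call(support, split=0, pos1=1000):
    frags = [_frag(pos1, 2000, f"f{i}") for i in range(support)]
    return cm.RearrangementCall(
        "chr1", pos1, "left", "chr2", 2000, "right", "t",
        support, split, None, 500, False, fragments=frags,
    )


class TestSelectCandidates:
    def test_strata_span_support_range(self):
        calls = [_call(s, pos1=1000 + 10 * s) for s in range(1, 21)]
        chosen, notice = select_candidates(calls, k=5)
        assert notice is None and len(chosen) == 5
        supports = sorted(c.n_supporting_fragments for c in chosen)
        assert supports[0] <= 4 and supports[-1] >= 17  # min and max strata represented

    def test_shortfall_notice(self):
        calls = [_call(3), _call(4), _call(5)]
        chosen, notice = select_candidates(calls, k=6)
        assert len(chosen) == 3 and "3 calls" in notice

    def test_deterministic_tie_break_on_split_support(self):
        a = _call(5, split=3, pos1=5000)
        b = _call(5, split=1, pos1=1000)
        chosen, _ = select_candidates([a, b], k=1)
        assert chosen == [a]

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            select_candidates([], k=0)
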