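"""Ping-pong network grouping, flank checks, and the snetDNA graph."""

import pytest

from pirnet.io import TranscriptAlignment
from pirnet.network import (
    build_snet_network,
    flank_unique_check,
    group_pingpong_networks,
    snet_edge_table,
)
from pirnet.phasing import BackTarget, TriggerEvent


def _event(eid, source, target, back="none", distance=None, anneal=200):
    return TriggerEvent(
        event_id=eid, trigger_read_id=f"{eid}_trig", source_transcript=source,
        trigger_five_prime=100, target_transcript=target,
        anneal_site=TranscriptAlignment(
            f"{eid}_trig", target, "antisense", anneal, 26, 2
        ),
        cleavage_pos=anneal - 9, trigger_rpm=10.0, responder_ids=("r",),
        responder_rpm=50.0, responder_rpm_unique=50.0, responder_pct1U=100.0,
        seed_mismatch_positions=(), perfect_seed=True,
        back_target=BackTarget(back, distance),
    )


class TestGrouping:
    def test_transitive_sharing_forms_one_network(self):
        nets = group_pingpong_networks(
            {"A": {"s1"}, "B": {"s1", "s2"}, "C": {"s2"}}
        )
        assert len(nets) == 1
        assert nets[0].members == ("A", "B", "C")

    def test_singletons_not_reported(self):
        assert group_pingpong_networks({"A": {"s1"}, "B": {"s2"}}) == []

    def test_invariant_to_input_order(self):
        a = {"A": {"x"}, "B": {"x"}, "C": {"y"}, "D": {"y"}}
        b = dict(reversed(list(a.items())))
        nets_a = group_pingpong_networks(a)
        nets_b = group_pingpong_networks(b)
        assert [n.members for n in nets_a] == [n.members for n in nets_b]

    def test_min_shared_floor(self):
        seqs = {"A": {"s1", "s2"}, "B": {"s1"}}
        assert len(group_pingpong_networks(seqs, min_shared=1)) == 1
        assert group_pingpong_networks(seqs, min_shared=2) == []

    def test_simulated_repeat_families_match_manifest(self, default_world, default_run):
        expected = {members for _, members in default_world.manifest.networks}
        assert {n.members for n in default_run.networks} == expected


class TestFlankCheck:
    LOCI = {"t": ("chr1", 20_000, 22_000, "+")}
    GENOME = {"chr1": 50_000}

    def _check(self, placements, flank=5000, min_rpm=0.5, total=2_000_000):
        return flank_unique_check(
            self.LOCI, placements, total, self.GENOME, flank, min_rpm
        )["t"]

    def test_exactly_half_rpm_is_false(self):
        # 1 copy in 2e6 genome-mapped = exactly 0.5 RPM: strict > fails
        assert self._check([("chr1", 21_000, 21_025, 1)]) is False
        assert self._check([("chr1", 21_000, 21_025, 2)]) is True

    def test_reads_only_in_downstream_flank_count(self):
        assert self._check([("chr1", 26_000, 26_025, 1000)]) is True
        assert self._check([("chr1", 28_000, 28_025, 1000)]) is False  # beyond flank

    def test_contig_shorter_than_flank_still_evaluated(self):
        loci = {"t": ("chr1", 100, 300, "+")}
        out = flank_unique_check(
            loci, [("chr1", 10, 35, 1000)], 1_000_000, {"chr1": 400}, 5000, 0.5
        )
        assert out["t"] is True

    def test_locus_without_coordinates_is_na(self):
        out = flank_unique_check({"t": None}, [], 1_000_000, {}, 5000, 0.5)
        assert out["t"] is None

    def test_enlarging_flank_never_flips_true_to_false(self):
        placements = [("chr1", 26_000, 26_025, 1000)]
        for flank in (5000, 10_000, 20_000):
            assert self._check(placements, flank=flank) is True


class TestSnetNetwork:
    def test_one_way_and_reciprocal_edge_labels(self):
        events = [
            _event("e1", "X", "Y"),
            _event("e2", "X", "Z", back="trans_pingpong", distance=0),
            _event("e3", "Z", "X", back="trans_pingpong", distance=0),
        ]
        graph = build_snet_network(events)
        assert graph.edges["X", "Y"]["kind"] == "one_way"
        assert graph.edges["X", "Z"]["kind"] == "trans_pingpong"
        table = snet_edge_table(graph)
        # reciprocal pair collapses to a single trans-ping-pong row
        assert (table["kind"] == "trans_pingpong").sum() == 1
        assert len(table) == 2

    def test_empty_events_give_empty_graph(self):
        graph = build_snet_network([])
        assert graph.number_of_nodes() == 0
        assert snet_edge_table(graph).empty

    def test_edge_conservation(self):
        events = [_event(f"e{i}", "X", t) for i, t in enumerate("ABC")]
        table = snet_edge_table(build_snet_network(events))
        assert table["n_events"].sum() == len(events)

    def test_fig_style_topology_recovered(self, default_run):
        table = snet_edge_table(default_run.snet_graph)
        kinds = dict(zip(zip(table["source"], table["target"]), table["kind"]))
        assert kinds[("snet_src", "snet_t1")] == "one_way"
        assert kinds[("snet_src", "snet_t3")] == "one_way"
        trans = {
            tuple(sorted((s, t)))
            for (s, t), k in kinds.items() if k == "trans_pingpong"
        }
        assert trans == {("snet_src", "snet_t2")}
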