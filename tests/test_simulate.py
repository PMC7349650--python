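"""Generator invariants: determinism, manifest completeness, planted geometry."""

import filecmp

import numpy as np
import pytest

from pirnet.simulate import (
    SimConfig,
    make_world,
    plant_pingpong,
    plant_trigger_event,
    write_world,
)
from pirnet._seq import revcomp

from conftest import random_dna

SMALL = dict(
    n_repeat_families=1, repeat_copies=2, n_intrinsic_pp=1,
    pp_pairs_per_transcript=32, intrinsic_pairs=32, n_plain_transcripts=0,
)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        for d in ("a", "b"):
            write_world(make_world(SimConfig(rng_seed=5, **SMALL)), tmp_path / d)
        files = [p.name for p in (tmp_path / "a").iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", files, shallow=False
        )
        assert sorted(match) == sorted(files) and not mismatch and not errors


class TestManifest:
    def test_every_read_in_exactly_one_category(self, default_world):
        m = default_world.manifest.reads
        assert sorted(m["read_id"]) == sorted(r.id for r in default_world.reads)
        assert m["count"].sum() == sum(r.count for r in default_world.reads)

    def test_noiseless_config_with_one_event(self):
        cfg = SimConfig(rng_seed=2, n_repeat_families=0, n_intrinsic_pp=0,
                        n_plain_transcripts=0)
        world = make_world(cfg)
        # three planted targets plus the reciprocal trans-ping-pong pair
        assert len(world.manifest.events) == 4

    def test_responder_overlap_geometry_holds_for_all_events(self, default_world):
        events = default_world.manifest.events
        reads = default_world.manifest.reads.set_index("read_id")
        for row in events.itertuples():
            resp = reads.loc[row.responder_read_id]
            assert row.cleavage_pos == row.anneal_five_prime - 9
            assert int(resp["five_prime"]) == row.cleavage_pos
            # 10-nt 5'-overlap between trigger and responder
            assert row.anneal_five_prime - int(resp["five_prime"]) + 1 == 10

    def test_halving_responder_depth_halves_responder_copies(self):
        base = make_world(SimConfig(rng_seed=7, **SMALL))
        half = make_world(SimConfig(rng_seed=7, responder_depth=25, **SMALL))

        def responder_copies(world):
            m = world.manifest.reads
            return m.loc[m["category"] == "responder", "count"].sum()

        assert responder_copies(base) == 2 * responder_copies(half)


class TestPlantPingpong:
    def test_full_1u_bias_realized(self, rng):
        seq = random_dna(rng, 1500)
        _, reads, _ = plant_pingpong(seq, 30, 1.0, 1.0, rng)
        anti = [r for r in reads if r.id.endswith("_as")]
        assert all(r.seq[0] == "T" for r in anti)
        sense = [r for r in reads if r.id.endswith("_s")]
        assert all(r.seq[9] == "A" for r in sense)

    def test_zero_pairs_no_reads(self, rng):
        seq = random_dna(rng, 500)
        out_seq, reads, rows = plant_pingpong(seq, 0, 0.9, 0.9, rng)
        assert out_seq == seq and reads == [] and rows == []

    def test_reads_map_edited_sequence_exactly(self, rng):
        seq = random_dna(rng, 1500)
        edited, reads, rows = plant_pingpong(seq, 20, 0.9, 0.9, rng)
        by_id = {row["read_id"]: row for row in rows}
        for r in reads:
            row = by_id[r.id]
            p = row["five_prime"]
            if row["strand"] == "sense":
                assert edited[p - 1 : p - 1 + r.length] == r.seq
            else:
                assert revcomp(edited[p - r.length : p]) == r.seq


class TestPlantTriggerEvent:
    def test_seed_avoiding_mismatches_give_perfect_seed(self, rng):
        out = plant_trigger_event(
            random_dna(rng, 2500), random_dna(rng, 2500),
            trigger_pos=301, anneal_window_start=401,
            mm_query_positions=(14, 20), rng=rng,
        )
        assert out["event_row"]["perfect_seed"]
        assert out["event_row"]["mismatches"] == 2

    def test_trail_chain_is_head_to_tail(self, rng):
        out = plant_trigger_event(
            random_dna(rng, 2500), random_dna(rng, 2500),
            trigger_pos=301, anneal_window_start=401,
            mm_query_positions=(14,), rng=rng, trail_len=5, trail_jitter=0,
        )
        rows = [r for r in out["read_rows"] if r["category"] == "trail"]
        reads = {r.id: r for r in out["reads"]}
        prev_end = out["event_row"]["cleavage_pos"] + 26 - 1  # responder 3'
        for row in rows:
            assert row["five_prime"] == prev_end + 1  # d = 1 phasing
            prev_end = row["five_prime"] + reads[row["read_id"]].length - 1

    def test_infeasible_window_raises(self, rng):
        with pytest.raises(ValueError, match="larger target"):
            plant_trigger_event(
                random_dna(rng, 2500), random_dna(rng, 300),
                trigger_pos=301, anneal_window_start=250,
                mm_query_positions=(14,), rng=rng,
            )

    def test_infeasible_repeat_config_rejected(self):
        with pytest.raises(ValueError, match="repeat lengths"):
            SimConfig(repeat_len_range=(100, 1130)).validate()
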