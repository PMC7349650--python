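"""Trigger/responder geometry, seed profiling, trail phasing, back-targeting."""

import math

import numpy as np
import pytest

from pirnet.io import ANTISENSE, SENSE, SmallRead, Transcript, TranscriptAlignment
from pirnet.phasing import (
    BackTarget,
    candidate_targets,
    classify_back_targeting,
    detect_trail,
    find_trigger_sites,
    pair_responders,
    seed_profile,
)
from pirnet._seq import revcomp

from conftest import random_dna

TOTAL_GM = 1_000_000


def _site(fp, mm=(), length=26):
    return TranscriptAlignment(
        "trig", "target", ANTISENSE, fp, length,
        mismatches=len(mm), mismatch_positions=tuple(mm),
    )


def _sense(rid, fp, length=26, tid="target"):
    return TranscriptAlignment(rid, tid, SENSE, fp, length)


class TestCandidateTargets:
    def test_strictly_above_three_rpm(self):
        table = {"at_bound": 3.0, "above": 3.1, "below": 0.5}
        assert candidate_targets(table) == ["above"]

    def test_empty_table(self):
        assert candidate_targets({}) == []


class TestSeedProfile:
    def test_mismatches_outside_seed_keep_it_perfect(self):
        positions, perfect = seed_profile(_site(200, mm=(14, 20)))
        assert positions == () and perfect

    def test_mismatch_at_five_breaks_the_seed(self):
        positions, perfect = seed_profile(_site(200, mm=(5, 14)))
        assert positions == (5,) and not perfect


class TestPairResponders:
    def test_cleavage_geometry(self):
        reads = {
            "resp": SmallRead("resp", "T" + "C" * 25, count=10),
            "off": SmallRead("off", "G" + "C" * 25, count=10),
        }
        site = _site(200)
        alns = [_sense("resp", 191), _sense("off", 192)]
        ids, resp_rpm, resp_rpm_u, pct1u = pair_responders(
            site, alns, reads, {r.seq: 1 for r in reads.values()}, TOTAL_GM
        )
        assert ids == ("resp",)  # 5' = 200 - 9 = 191; 192 is not a responder
        assert resp_rpm == pytest.approx(10.0)
        assert resp_rpm_u == pytest.approx(10.0)
        assert pct1u == 100.0
        # 10-nt 5'-overlap between trigger and responder
        assert site.five_prime - 191 + 1 == 10

    def test_non_unique_responders_counted_in_both_tallies(self):
        reads = {"resp": SmallRead("resp", "T" + "C" * 25, count=8)}
        ids, resp_rpm, resp_rpm_u, _ = pair_responders(
            _site(200), [_sense("resp", 191)], reads,
            {reads["resp"].seq: 2}, TOTAL_GM,
        )
        assert resp_rpm == pytest.approx(8.0)
        assert resp_rpm_u == 0.0


class TestFindTriggerSites:
    def test_self_locus_excluded_and_mm_bounds_enforced(self, rng):
        source_seq = random_dna(rng, 300)
        trigger = SmallRead("trig", source_seq[100:126])
        # perfect complement on the target: excluded at mm range [1, 5]
        target_seq = (
            random_dna(rng, 100) + revcomp(trigger.seq) + random_dna(rng, 100)
        )
        source = Transcript("source", source_seq)
        target = Transcript("perfect_target", target_seq)
        sites = find_trigger_sites(
            [trigger], {"trig": {"source"}}, [source, target], (1, 5)
        )
        assert sites == []
        # two mismatches: found, with positions reported
        mutated = list(revcomp(trigger.seq))
        subst = {"A": "C", "C": "G", "G": "T", "T": "A"}
        mutated[2] = subst[mutated[2]]
        mutated[9] = subst[mutated[9]]
        target2 = Transcript(
            "mm_target", random_dna(rng, 50) + "".join(mutated) + random_dna(rng, 50)
        )
        (site,) = find_trigger_sites(
            [trigger], {"trig": {"source"}}, [source, target2], (1, 5)
        )
        assert site.mismatches == 2
        assert site.five_prime == 76
        assert set(site.mismatch_positions) == {26 - 2, 26 - 9}


class TestDetectTrail:
    def test_head_to_tail_adjacency_is_distance_one(self):
        reads = {
            "resp": SmallRead("resp", "T" * 26, count=1),
            "trail": SmallRead("trail", "T" * 26, count=1),
        }
        alns = [_sense("resp", 191), _sense("trail", 217)]  # resp spans 191-216
        profile = detect_trail(191, alns, reads, 2000, TOTAL_GM)
        assert profile.hist[0] == 1.0
        assert profile.trail_pct1U == 100.0

    def test_no_downstream_reads_gives_empty_profile(self):
        reads = {"resp": SmallRead("resp", "T" * 26, count=1)}
        profile = detect_trail(191, [_sense("resp", 191)], reads, 2000, TOTAL_GM)
        assert profile.hist.sum() == 0
        assert math.isnan(profile.z1) and profile.degenerate

    def test_window_truncated_at_transcript_end(self):
        reads = {"resp": SmallRead("resp", "T" * 26, count=1)}
        profile = detect_trail(191, [_sense("resp", 191)], reads, 500, TOTAL_GM)
        assert profile.truncated


class TestBackTargeting:
    def _plant(self, rng, implied_cleavage, trigger_fp, mm=2):
        """Source with a responder complement whose implied cleavage sits at
        ``implied_cleavage`` (1-based)."""
        source = list(random_dna(rng, 600))
        responder = SmallRead("resp", random_dna(rng, 26))
        site = list(revcomp(responder.seq))
        subst = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for j in range(mm):
            site[j] = subst[site[j]]
        start0 = implied_cleavage + 9 - 26  # anneal 5' = cleavage + 9
        source[start0 : start0 + 26] = site
        return responder, Transcript("src", "".join(source))

    def test_cleavage_at_trigger_locus_is_trans_pingpong(self, rng):
        responder, source = self._plant(rng, implied_cleavage=301, trigger_fp=301)
        back = classify_back_targeting([responder], source, 301)
        assert back.kind == "trans_pingpong"

    def test_hit_113_nt_downstream_of_trigger(self, rng):
        responder, source = self._plant(rng, implied_cleavage=414, trigger_fp=301, mm=5)
        back = classify_back_targeting([responder], source, 301)
        assert back == BackTarget("downstream_backtarget", 113)

    def test_no_complementarity_is_none(self, rng):
        source = Transcript("src", random_dna(rng, 600))
        back = classify_back_targeting(
            [SmallRead("resp", random_dna(rng, 26))], source, 301
        )
        assert back.kind == "none"
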