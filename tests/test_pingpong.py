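"""Ping-pong overlap statistics, base signatures, and classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirnet.io import ANTISENSE, SENSE, SmallRead, Transcript, TranscriptAlignment
from pirnet.pingpong import (
    base_signature,
    call_significance,
    classify_transcript,
    is_biased,
    matches_te,
    overlap_pair_counts,
    pingpong_partners,
    pingpong_z,
    te_and_repeat_attribution,
    trans_pingpong_scan,
)
from pirnet._seq import revcomp, seq_to_array

from conftest import random_dna


def naive_overlap_counts(sense, anti, d_max=24):
    counts = np.zeros(d_max)
    for p, s in sense.items():
        for q, a in anti.items():
            d = q - p + 1
            if 1 <= d <= d_max:
                counts[d - 1] += s * a
    return counts


class TestOverlapPairCounts:
    def test_ten_nt_overlap_lands_in_bin_ten(self):
        counts = overlap_pair_counts({100: 1}, {109: 1})
        assert counts[9] == 1 and counts.sum() == 1

    def test_coincident_five_primes_is_one_nt_overlap(self):
        counts = overlap_pair_counts({100: 1}, {100: 1})
        assert counts[0] == 1 and counts.sum() == 1

    def test_negative_direction_not_counted(self):
        assert overlap_pair_counts({100: 1}, {95: 1}).sum() == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        sense, anti = {}, {}
        for p in rng.integers(1, 500, size=50):
            sense[int(p)] = sense.get(int(p), 0) + 1
        for p in rng.integers(1, 500, size=50):
            anti[int(p)] = anti.get(int(p), 0) + 1
        assert np.array_equal(
            overlap_pair_counts(sense, anti), naive_overlap_counts(sense, anti)
        )


class TestPingPongZ:
    def test_single_loaded_bin(self):
        counts = np.zeros(24)
        counts[9] = 24
        z, degenerate = pingpong_z(counts)
        assert not degenerate
        assert z == pytest.approx(23 / math.sqrt(23))  # ~4.796

    def test_flat_bins_give_zero_and_are_flagged(self):
        z, degenerate = pingpong_z(np.full(24, 5.0))
        assert (z, degenerate) == (0.0, True)

    def test_all_zero_is_degenerate_and_not_significant(self):
        z, degenerate = pingpong_z(np.zeros(24))
        assert degenerate and math.isnan(z)
        assert not call_significance(z, 0)


class TestSignificanceBoundary:
    @pytest.mark.parametrize(
        "z, pairs, expected",
        [(2.0, 30, True), (1.96, 100, False), (5.0, 29, False)],
    )
    def test_strict_z_and_inclusive_pair_floor(self, z, pairs, expected):
        assert call_significance(z, pairs) is expected


class TestBaseSignature:
    def test_t_at_one_and_a_at_ten(self):
        reads = [SmallRead("r", "T" + "A" * 23)]
        assert base_signature(reads) == (100.0, 100.0)

    def test_absent_signature(self):
        reads = [SmallRead("r", "G" + "A" * 8 + "GC" + "A" * 13)]
        assert base_signature(reads) == (0.0, 0.0)

    def test_exactly_half_is_not_biased(self):
        assert not is_biased(50.0)
        assert is_biased(50.1)

    def test_empty_set_is_na(self):
        pct1u, pct10a = base_signature([])
        assert math.isnan(pct1u) and math.isnan(pct10a)

    def test_collapsed_vs_noncollapsed_weighting(self):
        reads = [SmallRead("a", "T" + "C" * 25, count=9),
                 SmallRead("b", "G" + "C" * 25, count=1)]
        assert base_signature(reads, weighted=True)[0] == 90.0
        assert base_signature(reads, weighted=False)[0] == 50.0


class TestPingPongPartners:
    def _aln(self, rid, strand, fp):
        return TranscriptAlignment(rid, "t", strand, fp, 26)

    def test_d10_pair_flags_both(self):
        alns = [self._aln("s", SENSE, 100), self._aln("a", ANTISENSE, 109)]
        assert pingpong_partners(alns) == ({"s"}, {"a"})

    def test_lone_read_not_flagged(self):
        assert pingpong_partners([self._aln("s", SENSE, 100)]) == (set(), set())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_pairwise_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        alns = [
            self._aln(f"s{i}", SENSE, int(p))
            for i, p in enumerate(rng.integers(1, 200, size=30))
        ] + [
            self._aln(f"a{i}", ANTISENSE, int(p))
            for i, p in enumerate(rng.integers(1, 200, size=30))
        ]
        expect_s, expect_a = set(), set()
        for x in alns:
            for y in alns:
                if x.strand == SENSE and y.strand == ANTISENSE:
                    if y.five_prime - x.five_prime + 1 == 10:
                        expect_s.add(x.read_id)
                        expect_a.add(y.read_id)
        assert pingpong_partners(alns) == (expect_s, expect_a)


class TestTeAttribution:
    def test_mismatch_ceiling_at_three(self, rng):
        te = Transcript("TE1", random_dna(rng, 300))
        arr = [seq_to_array(te.seq)]
        window = list(te.seq[50:76])
        subst = {"A": "C", "C": "G", "G": "T", "T": "A"}
        for k in (1, 2, 3):
            window[k] = subst[window[k]]
        assert matches_te("".join(window), arr, max_mm=3)
        window[10] = subst[window[10]]  # 4th mismatch
        assert not matches_te("".join(window), arr, max_mm=3)

    def test_repeat_share_counts_multiplicity_two_or_more(self, rng):
        reads = [SmallRead("u", random_dna(rng, 26)), SmallRead("m", random_dna(rng, 26))]
        mult = {reads[0].seq: 1, reads[1].seq: 3}
        pct_te, pct_rep = te_and_repeat_attribution(reads, None, mult)
        assert math.isnan(pct_te)  # no TE library
        assert pct_rep == 50.0


class TestClassification:
    @pytest.mark.parametrize(
        "significant, pct_unique, expected",
        [(False, 100.0, "noPP"), (True, 100.0, "uniquePP"),
         (True, 96.0, "uniquePP"), (True, 95.0, "repeatPP"),
         (True, 40.0, "repeatPP")],
    )
    def test_unique_threshold_strict_above_95(self, significant, pct_unique, expected):
        assert classify_transcript(significant, pct_unique) == expected


class TestTransPingPong:
    def test_planted_external_partner_with_two_mismatches(self, rng):
        t_seq = random_dna(rng, 400)
        t = Transcript("t", t_seq)
        # sense read 5' at 101; external trigger anneals with its 5' at 110
        ext = list(revcomp(t_seq[84:110]))  # anneal 5' = 110 (1-based)
        subst = {"A": "C", "C": "G", "G": "T", "T": "A"}
        ext[3] = subst[ext[3]]
        ext[7] = subst[ext[7]]
        hits = trans_pingpong_scan(
            t, {101: 2.0}, [SmallRead("ext", "".join(ext))], max_mm=5
        )
        assert any(h.five_prime == 110 and h.mismatches == 2 for h in hits)

    def test_no_external_reads_gives_empty(self, rng):
        t = Transcript("t", random_dna(rng, 100))
        assert trans_pingpong_scan(t, {10: 1.0}, []) == []
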