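"""Trigger -> responder -> trail inference (phased piRNA biogenesis).

A genome-unique piRNA mapping a transcript sense at 0 mismatches (its
source locus therefore known) may anneal another transcript in a
reverse-complementary manner with 1-5 mismatches.  Such a trigger guides
slicing of the target between its own nucleotides 10 and 11, so the
responder piRNAs born from the cut start exactly 9 nt upstream of the
coordinate facing the trigger 5' end:

    cleavage_pos = anneal_site.five_prime - 9
    (trigger 5' to responder 5' overlap == 10 nt)

This geometry holds even when base pairing only starts at trigger position
2 or 3.  Downstream of the responder, phased trail piRNAs follow
head-to-tail (3' end to next 5' end distance of 1 nt), typically 1U-biased.

The trail statistic reported here (z-score of the d=1 bin over head-to-tail
distances 1..50) is a surrogate summary defined by this package; outputs
label it as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .filtering import rpm
from .io import (
    SENSE,
    SmallRead,
    Transcript,
    TranscriptAlignment,
    search_rc_mismatched,
)
from .pingpong import pingpong_z

SEED_RANGE = range(2, 12)  # trigger positions 2..11 (the putative seed)
TRAIL_D_MAX = 50
DEFAULT_TRAIL_WINDOW = 1000
DEFAULT_MIN_RPM = 3.0
DEFAULT_MM_RANGE = (1, 5)


@dataclass(frozen=True)
class BackTarget:
    """Back-targeting of the source transcript by an event's responders.

    ``trans_pingpong``: a responder annealing site on the source implies a
    cleavage position coinciding with the original trigger's 5' locus
    (reciprocal amplification).  ``downstream_backtarget``: responders hit
    the source elsewhere; ``distance`` is the signed offset (nt) of the
    implied cleavage from the trigger locus.  ``none``: no complementarity
    within the mismatch allowance.
    """

    kind: str  # {trans_pingpong, downstream_backtarget, none}
    distance: int | None = None


@dataclass
class PhasingProfile:
    """Head-to-tail distance histogram downstream of a cleavage site."""

    hist: np.ndarray  # bins d = 1..TRAIL_D_MAX
    z1: float
    degenerate: bool
    trail_rpm: float
    trail_pct1U: float
    truncated: bool = False

    @property
    def n_trail_reads(self) -> float:
        return float(self.hist.sum())


@dataclass
class TriggerEvent:
    """One trigger annealing site with its responder and trail sets."""

    event_id: str
    trigger_read_id: str
    source_transcript: str
    trigger_five_prime: int  # trigger 5' position on its source (sense)
    target_transcript: str
    anneal_site: TranscriptAlignment
    cleavage_pos: int
    trigger_rpm: float
    responder_ids: tuple[str, ...]
    responder_rpm: float
    responder_rpm_unique: float
    responder_pct1U: float
    seed_mismatch_positions: tuple[int, ...]
    perfect_seed: bool
    back_target: BackTarget = field(default_factory=lambda: BackTarget("none"))
    trail: PhasingProfile | None = None


def candidate_targets(
    unique_sense_rpm: Mapping[str, float], min_rpm: float = DEFAULT_MIN_RPM
) -> list[str]:
    """Transcripts matching strictly more than ``min_rpm`` RPM of
    genome-unique sense-oriented piRNAs without mismatch."""
    return sorted(t for t, v in unique_sense_rpm.items() if v > min_rpm)


def find_trigger_sites(
    query_reads: Sequence[SmallRead],
    source_by_read: Mapping[str, set[str]],
    targets: Sequence[Transcript],
    mm_range: tuple[int, int] = DEFAULT_MM_RANGE,
) -> list[TranscriptAlignment]:
    """Antisense annealing sites of genome-unique genic piRNAs on candidate
    targets within the mismatch range; hits on a query's own source
    transcript(s) are excluded."""
    sites = search_rc_mismatched(query_reads, targets, *mm_range)
    return [
        s for s in sites
        if s.transcript_id not in source_by_read.get(s.read_id, set())
    ]


def seed_profile(site: TranscriptAlignment) -> tuple[tuple[int, ...], bool]:
    """Mismatch positions falling in the putative seed (trigger positions
    2-11) and whether the seed is perfectly matched."""
    in_seed = tuple(p for p in site.mismatch_positions if p in SEED_RANGE)
    return in_seed, len(in_seed) == 0


def pair_responders(
    anneal_site: TranscriptAlignment,
    target_sense_alignments: Sequence[TranscriptAlignment],
    reads_by_id: Mapping[str, SmallRead],
    multiplicity_by_seq: Mapping[str, int],
    total_genome_mapped: int,
) -> tuple[tuple[str, ...], float, float, float]:
    """Responders of an annealing site: sense 0-mm reads whose 5' equals the
    implied cleavage position (10-nt 5'-overlap with the trigger).

    Returns (responder read ids, responder RPM, genome-unique responder RPM,
    responder pct1U).  Responders need not be genome-unique; both tallies
    are reported.
    """
    cleavage = anneal_site.five_prime - 9
    ids = sorted({
        a.read_id for a in target_sense_alignments
        if a.strand == SENSE and a.five_prime == cleavage
    })
    reads = [reads_by_id[i] for i in ids]
    total = sum(r.count for r in reads)
    uniq = sum(r.count for r in reads if multiplicity_by_seq.get(r.seq, 0) == 1)
    n1u = sum(r.count for r in reads if r.seq[0] == "T")
    pct1u = 100.0 * n1u / total if total else float("nan")
    return (
        tuple(ids),
        rpm(total, total_genome_mapped),
        rpm(uniq, total_genome_mapped),
        pct1u,
    )


def detect_trail(
    cleavage_pos: int,
    target_sense_alignments: Sequence[TranscriptAlignment],
    reads_by_id: Mapping[str, SmallRead],
    transcript_length: int,
    total_genome_mapped: int,
    window_nt: int = DEFAULT_TRAIL_WINDOW,
    d_max: int = TRAIL_D_MAX,
) -> PhasingProfile:
    """Phasing profile downstream of a cleavage position.

    Sense reads with 5' in (cleavage_pos, cleavage_pos + window_nt] are the
    trail candidates; the histogram collects head-to-tail distances
    d = next_5' - prev_3' in 1..d_max over ordered read pairs, seeding the
    chain with the responders (5' == cleavage_pos).  The z-score of d = 1 is
    computed like the ping-pong z over bins 1..d_max.
    """
    truncated = cleavage_pos + window_nt > transcript_length
    hi = min(cleavage_pos + window_nt, transcript_length)
    chain = [
        a for a in target_sense_alignments
        if a.strand == SENSE and cleavage_pos <= a.five_prime <= hi
    ]
    trail = [a for a in chain if a.five_prime > cleavage_pos]
    w = {a.read_id: reads_by_id[a.read_id].count for a in chain}
    hist = np.zeros(d_max, dtype=float)
    for u in chain:
        for v in trail:
            d = v.five_prime - u.three_prime
            if 1 <= d <= d_max:
                hist[d - 1] += w[u.read_id] * w[v.read_id]
    if hist.sum() == 0:
        z1, degenerate = float("nan"), True
    else:
        z1, degenerate = pingpong_z(hist, signal_bin=1)
    trail_reads = {a.read_id: reads_by_id[a.read_id] for a in trail}
    total = sum(r.count for r in trail_reads.values())
    n1u = sum(r.count for r in trail_reads.values() if r.seq[0] == "T")
    return PhasingProfile(
        hist=hist,
        z1=z1,
        degenerate=degenerate,
        trail_rpm=rpm(total, total_genome_mapped),
        trail_pct1U=100.0 * n1u / total if total else float("nan"),
        truncated=truncated,
    )


def classify_back_targeting(
    responder_reads: Sequence[SmallRead],
    source_transcript: Transcript,
    trigger_five_prime: int,
    max_mm: int = 5,
) -> BackTarget:
    """Do an event's responders target back the trigger-producing transcript?

    Responders are searched reverse-complementarily (0..max_mm mismatches)
    against the source; a hit whose implied cleavage position coincides with
    the trigger's 5' locus means reciprocal (trans-ping-pong) amplification,
    any other hit is a downstream/offset back-target reported with its
    signed distance from the trigger locus.
    """
    if not responder_reads:
        return BackTarget("none")
    hits = search_rc_mismatched(responder_reads, [source_transcript], 0, max_mm)
    distances = []
    for h in hits:
        implied_cleavage = h.five_prime - 9
        if implied_cleavage == trigger_five_prime:
            return BackTarget("trans_pingpong", 0)
        distances.append(implied_cleavage - trigger_five_prime)
    if distances:
        best = min(distances, key=lambda d: (abs(d), d))
        return BackTarget("downstream_backtarget", best)
    return BackTarget("none")


def infer_trigger_events(
    reads: Sequence[SmallRead],
    transcripts: Sequence[Transcript],
    alignments: Sequence[TranscriptAlignment],
    multiplicity_by_seq: Mapping[str, int],
    total_genome_mapped: int,
    min_rpm: float = DEFAULT_MIN_RPM,
    mm_range: tuple[int, int] = DEFAULT_MM_RANGE,
    trail_window: int = DEFAULT_TRAIL_WINDOW,
    backtarget_max_mm: int = 5,
) -> list[TriggerEvent]:
    """End-to-end trigger-event inference on collapsed reads.

    Trigger queries are all genome-unique reads mapping a transcript sense
    at 0 mismatches; candidate targets are transcripts matching > min_rpm
    RPM of genome-unique sense piRNAs; events are retained when the
    responder RPM exceeds min_rpm.  A read may act as responder in one
    event and trigger of another (no exclusivity).
    """
    reads_by_id = {r.id: r for r in reads}
    t_by_id = {t.id: t for t in transcripts}
    sense_by_tid: dict[str, list[TranscriptAlignment]] = {}
    source_by_read: dict[str, set[str]] = {}
    for a in alignments:
        if a.strand == SENSE:
            sense_by_tid.setdefault(a.transcript_id, []).append(a)
            read = reads_by_id.get(a.read_id)
            if read is not None and multiplicity_by_seq.get(read.seq, 0) == 1:
                source_by_read.setdefault(a.read_id, set()).add(a.transcript_id)

    unique_sense_rpm = {
        tid: rpm(
            sum(
                reads_by_id[a.read_id].count
                for a in alns
                if multiplicity_by_seq.get(reads_by_id[a.read_id].seq, 0) == 1
            ),
            total_genome_mapped,
        )
        for tid, alns in sense_by_tid.items()
    }
    targets = [
        t_by_id[tid] for tid in candidate_targets(unique_sense_rpm, min_rpm)
    ]
    queries = [reads_by_id[rid] for rid in sorted(source_by_read)]
    queries = [q for q in queries if q.length >= 10]
    sites = find_trigger_sites(queries, source_by_read, targets, mm_range)

    # trigger 5' positions on each source transcript (first sense alignment)
    trigger_pos: dict[tuple[str, str], int] = {}
    for a in alignments:
        if a.strand == SENSE:
            trigger_pos.setdefault((a.read_id, a.transcript_id), a.five_prime)

    events: list[TriggerEvent] = []
    for site in sorted(
        sites, key=lambda s: (s.read_id, s.transcript_id, s.five_prime)
    ):
        ids, resp_rpm, resp_rpm_u, pct1u = pair_responders(
            site,
            sense_by_tid.get(site.transcript_id, []),
            reads_by_id,
            multiplicity_by_seq,
            total_genome_mapped,
        )
        if resp_rpm <= min_rpm:
            continue
        cleavage = site.five_prime - 9
        seed_mm, perfect = seed_profile(site)
        target = t_by_id[site.transcript_id]
        trail = detect_trail(
            cleavage,
            sense_by_tid.get(site.transcript_id, []),
            reads_by_id,
            target.length,
            total_genome_mapped,
            window_nt=trail_window,
        )
        responder_reads = [reads_by_id[i] for i in ids]
        back = BackTarget("none")
        src_used = None
        for src_tid in sorted(source_by_read[site.read_id]):
            bt = classify_back_targeting(
                responder_reads,
                t_by_id[src_tid],
                trigger_pos[(site.read_id, src_tid)],
                max_mm=backtarget_max_mm,
            )
            if src_used is None or (
                bt.kind == "trans_pingpong" and back.kind != "trans_pingpong"
            ) or (bt.kind != "none" and back.kind == "none"):
                back, src_used = bt, src_tid
        events.append(
            TriggerEvent(
                event_id=f"evt_{len(events) + 1}",
                trigger_read_id=site.read_id,
                source_transcript=src_used,
                trigger_five_prime=trigger_pos[(site.read_id, src_used)],
                target_transcript=site.transcript_id,
                anneal_site=site,
                cleavage_pos=cleavage,
                trigger_rpm=rpm(
                    reads_by_id[site.read_id].count, total_genome_mapped
                ),
                responder_ids=ids,
                responder_rpm=resp_rpm,
                responder_rpm_unique=resp_rpm_u,
                responder_pct1U=pct1u,
                seed_mismatch_positions=seed_mm,
                perfect_seed=perfect,
                back_target=back,
                trail=trail,
            )
        )
    return events


def events_to_frame(events: Sequence[TriggerEvent]):
    """Events as a flat pandas DataFrame (one row per trigger/responder pair)."""
    import pandas as pd

    rows = []
    for e in events:
        rows.append({
            "event_id": e.event_id,
            "trigger_read_id": e.trigger_read_id,
            "source_transcript": e.source_transcript,
            "trigger_five_prime": e.trigger_five_prime,
            "target_transcript": e.target_transcript,
            "anneal_five_prime": e.anneal_site.five_prime,
            "trigger_rpm": e.trigger_rpm,
            "mismatches": e.anneal_site.mismatches,
            "mismatch_positions": ",".join(map(str, e.anneal_site.mismatch_positions)) or ".",
            "cleavage_pos": e.cleavage_pos,
            "n_responders": len(e.responder_ids),
            "responder_rpm": e.responder_rpm,
            "responder_rpm_unique": e.responder_rpm_unique,
            "responder_pct1U": e.responder_pct1U,
            "seed_mismatch_positions": ",".join(map(str, e.seed_mismatch_positions)) or ".",
            "perfect_seed": e.perfect_seed,
            "back_target": e.back_target.kind,
            "back_target_distance": (
                e.back_target.distance if e.back_target.distance is not None else ""
            ),
            # surrogate trail statistic defined by this package
            "trail_z1_surrogate": e.trail.z1 if e.trail else float("nan"),
            "trail_rpm": e.trail.trail_rpm if e.trail else 0.0,
            "trail_pct1U": e.trail.trail_pct1U if e.trail else float("nan"),
        })
    cols = [
        "event_id", "trigger_read_id", "source_transcript", "trigger_five_prime",
        "target_transcript", "anneal_five_prime", "trigger_rpm", "mismatches",
        "mismatch_positions", "cleavage_pos", "n_responders", "responder_rpm",
        "responder_rpm_unique", "responder_pct1U", "seed_mismatch_positions",
        "perfect_seed", "back_target", "back_target_distance",
        "trail_z1_surrogate", "trail_rpm", "trail_pct1U",
    ]
    return pd.DataFrame(rows, columns=cols)
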