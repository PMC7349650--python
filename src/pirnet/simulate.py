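"""Seeded synthetic worlds with planted piRNA structure.

The generator emits a genome, transcripts embedded in it at recorded loci,
and a small-RNA library in which every read is planted by a generative rule
mirroring piRNA biogenesis, together with a ground-truth manifest:

* **ping-pong networks** — families of transcripts sharing a repeat
  (130-1130 nt); sense/antisense read pairs with exact 10-nt 5'-overlaps
  are planted inside the repeat, so the same read sequences map every
  family member (genome-repeated, hence ``repeatPP``);
* **intrinsic ping-pong** — transcripts whose d=10 pairs are built from
  genome-unique sequence (``uniquePP``);
* **snetDNA trigger events** — a source transcript emits genome-unique
  trigger reads; a short (~25-42 nt) motif reverse-complementary to each
  trigger, with a configured number of mismatches, is written into a
  target; responder reads start at the implied cleavage position
  (anneal 5' - 9, i.e. a 10-nt 5'-overlap with the trigger) and 1U-biased
  trail reads chain head-to-tail downstream.  One target's responders are
  made complementary to the source at the trigger locus (trans-ping-pong)
  and another's at a configurable downstream offset (back-targeting);
* optional uniform background noise and structural-RNA contaminants.

Planting edits the transcript sequence before any read is extracted, so
every emitted read maps its transcript at 0 mismatches and the configured
Hamming distances of the mismatched annealing sites are exact.

Base-bias coupling: in a d=10 pair the sense position-10 base and the
antisense position-1 base are the same transcript nucleotide (the 10A of
one strand faces the 1U of the other), so those two probabilities cannot
be set independently; the generator drives the shared base with
max(p10A_sense, p1U_antisense).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._seq import revcomp
from .io import (
    SmallRead,
    Transcript,
    write_bed,
    write_fasta,
    write_fastq,
)

BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimConfig:
    """Study conditions for one synthetic world.

    Defaults define the noiseless reference world: 3 repeat families of 3
    member transcripts each, 2 intrinsic ping-pong transcripts, and one
    snetDNA network (one source, three targets) containing one
    trans-ping-pong pair and one downstream back-target at 113 nt.
    """

    rng_seed: int = 0
    # layout
    chrom_name: str = "chr1"
    intergenic_gap: int = 12_000  # > 2x the 5-kb flank, so flanks never collide
    transcript_len: int = 2_500
    read_len_range: tuple[int, int] = (24, 29)
    # ping-pong networks
    n_repeat_families: int = 3
    repeat_copies: int = 3
    repeat_len_range: tuple[int, int] = (130, 1130)
    pp_pairs_per_transcript: int = 40
    pp_pair_count: int = 3
    # intrinsic ping-pong
    n_intrinsic_pp: int = 2
    intrinsic_pairs: int = 40
    intrinsic_pair_count: int = 2
    p10A_sense: float = 0.9
    p1U_antisense: float = 0.9
    # snetDNA trigger events
    snet: bool = True
    trigger_len: int = 26
    trigger_count: int = 10
    responder_len: int = 26
    responder_depth: int = 50
    trail_len: int = 5
    trail_read_count: int = 10
    p1U_trail: float = 0.9
    trail_jitter: int = 0
    event_mm: tuple[int, ...] = (2, 2, 3)  # per target (t1, t2, t3)
    seed_mm_target3: tuple[int, ...] = (5,)  # seed mismatch (positions 2-11)
    transpp_mm: int = 2
    backtarget_mm: int = 5  # 5 mismatches over the back-annealing site
    backtarget_distance: int = 113
    # producer-locus evidence in the flanks of network members
    flank_reads_per_locus: int = 2
    flank_read_count: int = 5
    # contaminants / noise
    background_reads: int = 0
    structural_reads: int = 0
    n_plain_transcripts: int = 2

    def validate(self) -> None:
        for p in (self.p10A_sense, self.p1U_antisense, self.p1U_trail):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1]: {p}")
        lo, hi = self.repeat_len_range
        if not 130 <= lo <= hi <= 1130:
            raise ValueError("repeat lengths must stay within [130, 1130] nt")
        if hi + 200 > self.transcript_len:
            raise ValueError(
                "infeasible config: repeat does not fit in the transcript "
                f"({hi} + margin > {self.transcript_len})"
            )
        if self.trigger_len < 10 or self.responder_len < 10:
            raise ValueError("trigger/responder reads must be >= 10 nt")


@dataclass
class TruthManifest:
    """Ground truth for one world; every emitted read appears in exactly one
    read-table row (category in {repeat_pp, intrinsic_pp, trigger, responder,
    trail, flank_unique, noise, structural})."""

    reads: pd.DataFrame
    transcript_classes: dict[str, str]
    networks: list[tuple[str, tuple[str, ...]]]
    events: pd.DataFrame
    flank_true: dict[str, bool]


@dataclass
class SimWorld:
    config: SimConfig
    genome: dict[str, str]
    transcripts: list[Transcript]
    reads: list[SmallRead]
    structural_refs: list[Transcript]
    te_library: list[Transcript]
    manifest: TruthManifest


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _mutate(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def plant_pingpong(
    seq: str,
    n_pairs: int,
    p10A_sense: float,
    p1U_antisense: float,
    rng: np.random.Generator,
    read_len_range: tuple[int, int] = (24, 29),
    id_prefix: str = "pp",
    count: int = 1,
) -> tuple[str, list[SmallRead], list[dict]]:
    """Plant ``n_pairs`` sense/antisense read pairs with exact 10-nt
    5'-overlaps into a sequence.

    Returns the edited sequence, the reads, and manifest rows holding each
    read's 5' position (1-based) and strand.  The shared signature base is
    driven by max(p10A_sense, p1U_antisense) — see the module docstring.
    """
    if n_pairs == 0:
        return seq, [], []
    lo, hi = read_len_range
    lo_pos, hi_pos = hi - 10, len(seq) - hi  # 0-based sense 5' bounds
    if hi_pos - lo_pos < n_pairs:
        raise ValueError("sequence too short for the requested pair count")
    positions = rng.choice(np.arange(lo_pos, hi_pos), size=n_pairs, replace=False)
    chars = list(seq)
    p_sig = max(p10A_sense, p1U_antisense)
    for p0 in positions:
        if rng.random() < p_sig:
            chars[p0 + 9] = "A"
        elif chars[p0 + 9] == "A":
            chars[p0 + 9] = ["C", "G", "T"][rng.integers(0, 3)]
    edited = "".join(chars)
    reads, rows = [], []
    for i, p0 in enumerate(positions):
        ls = int(rng.integers(lo, hi + 1))
        la = int(rng.integers(lo, hi + 1))
        sense_seq = edited[p0 : p0 + ls]
        anti_seq = revcomp(edited[p0 + 10 - la : p0 + 10])
        reads.append(SmallRead(f"{id_prefix}_{i}_s", sense_seq, count))
        reads.append(SmallRead(f"{id_prefix}_{i}_as", anti_seq, count))
        rows.append({"read_id": f"{id_prefix}_{i}_s", "strand": "sense",
                     "five_prime": int(p0) + 1})
        rows.append({"read_id": f"{id_prefix}_{i}_as", "strand": "antisense",
                     "five_prime": int(p0) + 10})
    return edited, reads, rows


def _apply_window_mm(
    window: list[str], mm_query_positions: Iterable[int], rng: np.random.Generator
) -> None:
    """Substitute bases at the given 1-based query positions of a planted
    reverse-complement window (query position q sits at window index L-q)."""
    L = len(window)
    for q in mm_query_positions:
        j = L - q
        window[j] = _mutate(window[j], rng)


def plant_trigger_event(
    source_seq: str,
    target_seq: str,
    trigger_pos: int,
    anneal_window_start: int,
    mm_query_positions: tuple[int, ...],
    rng: np.random.Generator,
    trigger_len: int = 26,
    responder_len: int = 26,
    trail_len: int = 5,
    p1U_trail: float = 0.9,
    trail_jitter: int = 0,
    read_len_range: tuple[int, int] = (24, 29),
    id_prefix: str = "evt",
    trigger_count: int = 10,
    responder_depth: int = 50,
    trail_read_count: int = 10,
    back_target: str = "none",  # {none, trans_pingpong, downstream}
    backtarget_distance: int = 113,
    backtarget_mm: int = 5,
) -> dict:
    """Plant one trigger -> responder -> trail event.

    ``trigger_pos`` is the 1-based 5' position of the trigger on the source
    (sense); ``anneal_window_start`` the 1-based start of the planted
    reverse-complement window on the target.  ``mm_query_positions`` are
    the 1-based trigger coordinates carrying mismatches (exact Hamming
    distance by construction).  ``back_target`` additionally writes a
    (mismatched) reverse complement of the responder into the source, at
    the trigger locus for trans-ping-pong or ``backtarget_distance`` nt
    downstream of it.

    Returns a dict with the edited source/target sequences, the planted
    reads, manifest read rows, and the expected event row.
    """
    Lt, Lr = trigger_len, responder_len
    tp0 = trigger_pos - 1
    w0 = anneal_window_start - 1
    src = list(source_seq)
    tgt = list(target_seq)
    if any(not 1 <= q <= Lt for q in mm_query_positions):
        raise ValueError("mismatch positions must lie within the trigger")
    if w0 + Lt + Lr + (trail_len + 1) * (read_len_range[1] + trail_jitter) > len(tgt):
        raise ValueError("no suitable target window: use a larger target")

    # trigger with 1U and 10A on its source
    src[tp0] = "T"
    src[tp0 + 9] = "A"
    trigger = "".join(src[tp0 : tp0 + Lt])

    # reverse-complement annealing window with the configured mismatches
    window = list(revcomp(trigger))
    _apply_window_mm(window, mm_query_positions, rng)
    tgt[w0 : w0 + Lt] = window

    anneal_5p = w0 + Lt  # 1-based highest covered coordinate
    cleavage = anneal_5p - 9  # 1-based responder 5'

    # trail bases (1U-biased), then extract responder + trail after all edits
    trail_specs = []
    pos0 = cleavage - 1 + Lr  # 0-based 5' of the first trail read
    for i in range(trail_len):
        if trail_jitter:
            pos0 += int(rng.integers(0, trail_jitter + 1))
        length = int(rng.integers(read_len_range[0], read_len_range[1] + 1))
        if rng.random() < p1U_trail:
            tgt[pos0] = "T"
        elif tgt[pos0] == "T":
            tgt[pos0] = ["A", "C", "G"][rng.integers(0, 3)]
        trail_specs.append((pos0, length))
        pos0 += length

    responder = "".join(tgt[cleavage - 1 : cleavage - 1 + Lr])

    # back-targeting: write revcomp(responder) into the source
    back_label, back_distance = "none", None
    if back_target == "trans_pingpong":
        # responder[0:10] already equals revcomp(trigger[0:10]); writing the
        # remaining upstream bases makes the implied cleavage == trigger 5'
        upstream = list(revcomp(responder))[: Lr - 10]
        # keep the last upstream base intact: it faces responder position 11,
        # i.e. the edge of the putative seed
        for j in sorted(rng.choice(len(upstream) - 1, size=2, replace=False)):
            upstream[j] = _mutate(upstream[j], rng)
        src[tp0 - (Lr - 10) : tp0] = upstream
        back_label, back_distance = "trans_pingpong", 0
    elif back_target == "downstream":
        site = list(revcomp(responder))
        for j in sorted(rng.choice(len(site), size=backtarget_mm, replace=False)):
            site[j] = _mutate(site[j], rng)
        # implied cleavage = trigger_pos + backtarget_distance
        start0 = tp0 + backtarget_distance + 9 - Lr + 1
        src[start0 : start0 + Lr] = site
        back_label, back_distance = "downstream_backtarget", backtarget_distance

    reads = [SmallRead(f"{id_prefix}_trigger", trigger, trigger_count),
             SmallRead(f"{id_prefix}_responder", responder, responder_depth)]
    rows = [
        {"read_id": f"{id_prefix}_trigger", "category": "trigger",
         "strand": "sense", "five_prime": trigger_pos},
        {"read_id": f"{id_prefix}_responder", "category": "responder",
         "strand": "sense", "five_prime": cleavage},
    ]
    for i, (pos0, length) in enumerate(trail_specs):
        seq = "".join(tgt[pos0 : pos0 + length])
        reads.append(SmallRead(f"{id_prefix}_trail_{i}", seq, trail_read_count))
        rows.append({"read_id": f"{id_prefix}_trail_{i}", "category": "trail",
                     "strand": "sense", "five_prime": pos0 + 1})

    event_row = {
        "trigger_read_id": f"{id_prefix}_trigger",
        "anneal_five_prime": anneal_5p,
        "cleavage_pos": cleavage,
        "mismatches": len(mm_query_positions),
        "perfect_seed": all(not 2 <= q <= 11 for q in mm_query_positions),
        "back_target": back_label,
        "back_target_distance": back_distance,
    }
    return {
        "source_seq": "".join(src),
        "target_seq": "".join(tgt),
        "reads": reads,
        "read_rows": rows,
        "event_row": event_row,
    }


def make_structural_decoys(rng: np.random.Generator) -> list[Transcript]:
    """Synthetic decoy structural RNAs (random sequences, not real
    accessions) standing in for miRNA/rRNA/snRNA/tRNA references."""
    specs = [("rRNA_decoy_1", 800), ("tRNA_decoy_1", 90),
             ("snRNA_decoy_1", 150), ("miRNA_decoy_1", 70)]
    return [Transcript(name, _random_dna(rng, n), kind="unannotated")
            for name, n in specs]


def make_te_decoys(rng: np.random.Generator, n: int = 2, length: int = 500) -> list[Transcript]:
    """Synthetic decoy transposon sequences (random, not real TE families)."""
    return [Transcript(f"TE_decoy_{i + 1}", _random_dna(rng, length),
                       kind="unannotated") for i in range(n)]


def simulate_null_positions(
    rng: np.random.Generator,
    transcript_len: int = 500,
    n_sense: int = 50,
    n_antisense: int = 50,
) -> tuple[dict[int, float], dict[int, float]]:
    """Uniformly placed 5' positions on one transcript (no planted
    structure), for null calibration of the ping-pong call."""
    sense: dict[int, float] = {}
    anti: dict[int, float] = {}
    for p in rng.integers(1, transcript_len + 1, size=n_sense):
        sense[int(p)] = sense.get(int(p), 0) + 1
    for p in rng.integers(1, transcript_len + 1, size=n_antisense):
        anti[int(p)] = anti.get(int(p), 0) + 1
    return sense, anti


def make_world(config: SimConfig | None = None) -> SimWorld:
    """Generate a complete synthetic world from a config (deterministic
    under ``config.rng_seed``)."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)

    transcripts: dict[str, str] = {}
    kinds: dict[str, str] = {}
    reads: list[SmallRead] = []
    read_rows: list[dict] = []
    classes: dict[str, str] = {}
    networks: list[tuple[str, tuple[str, ...]]] = []
    event_rows: list[dict] = []

    def add_reads(rs, rows, category, feature, tid):
        reads.extend(rs)
        for read, row in zip(rs, rows):
            read_rows.append({
                "read_id": read.id,
                "category": row.get("category", category),
                "feature_id": feature,
                "transcript_id": tid,
                "strand": row.get("strand", "."),
                "five_prime": row.get("five_prime", 0),
                "count": read.count,
                "length": read.length,
            })

    # --- ping-pong networks (shared repeats) -----------------------------
    for f in range(1, cfg.n_repeat_families + 1):
        rep_len = int(rng.integers(*cfg.repeat_len_range))
        repeat = _random_dna(rng, rep_len)
        n_pairs = min(cfg.pp_pairs_per_transcript, (rep_len - 2 * 29) // 2)
        repeat, fam_reads, fam_rows = plant_pingpong(
            repeat, n_pairs, cfg.p10A_sense, cfg.p1U_antisense, rng,
            cfg.read_len_range, id_prefix=f"fam{f}_pp", count=cfg.pp_pair_count,
        )
        members = []
        for m in range(1, cfg.repeat_copies + 1):
            tid = f"ppnet{f}_m{m}"
            offset = 150 + 80 * m
            body = _random_dna(rng, cfg.transcript_len - rep_len)
            transcripts[tid] = body[:offset] + repeat + body[offset:]
            kinds[tid] = "mRNA"
            classes[tid] = "repeatPP"
            members.append(tid)
            rows_m = [
                {**row, "five_prime": row["five_prime"] + offset}
                for row in fam_rows
            ]
            if m == 1:  # reads are emitted once; they map every member
                add_reads(fam_reads, rows_m, "repeat_pp", f"ppnet_{f}", tid)
        networks.append((f"ppnet_{f}", tuple(members)))

    # --- intrinsic ping-pong ---------------------------------------------
    for i in range(1, cfg.n_intrinsic_pp + 1):
        tid = f"intrinsic{i}"
        seq = _random_dna(rng, cfg.transcript_len)
        seq, rs, rows = plant_pingpong(
            seq, cfg.intrinsic_pairs, cfg.p10A_sense, cfg.p1U_antisense, rng,
            cfg.read_len_range, id_prefix=f"int{i}_pp",
            count=cfg.intrinsic_pair_count,
        )
        transcripts[tid] = seq
        kinds[tid] = "mRNA"
        classes[tid] = "uniquePP"
        add_reads(rs, rows, "intrinsic_pp", tid, tid)

    # --- snetDNA trigger events ------------------------------------------
    if cfg.snet:
        src_id = "snet_src"
        source = _random_dna(rng, cfg.transcript_len)
        target_specs = [
            ("snet_t1", "mRNA", "none", cfg.event_mm[0], ()),
            ("snet_t2", "lncRNA", "trans_pingpong", cfg.event_mm[1], ()),
            ("snet_t3", "mRNA", "downstream", cfg.event_mm[2],
             cfg.seed_mm_target3),
        ]
        trigger_positions = (301, 901, 1501)
        for j, (tid, kind, back, mm, seed_mm) in enumerate(target_specs):
            target = _random_dna(rng, cfg.transcript_len)
            n_outside = mm - len(seed_mm)
            outside = rng.choice(
                np.arange(12, cfg.trigger_len + 1), size=n_outside, replace=False
            )
            mm_positions = tuple(sorted(set(seed_mm) | set(int(q) for q in outside)))
            planted = plant_trigger_event(
                source, target,
                trigger_pos=trigger_positions[j],
                anneal_window_start=401,
                mm_query_positions=mm_positions,
                rng=rng,
                trigger_len=cfg.trigger_len,
                responder_len=cfg.responder_len,
                trail_len=cfg.trail_len,
                p1U_trail=cfg.p1U_trail,
                trail_jitter=cfg.trail_jitter,
                read_len_range=cfg.read_len_range,
                id_prefix=f"snet{j + 1}",
                trigger_count=cfg.trigger_count,
                responder_depth=cfg.responder_depth,
                trail_read_count=cfg.trail_read_count,
                back_target=back,
                backtarget_distance=cfg.backtarget_distance,
                backtarget_mm=cfg.backtarget_mm,
            )
            source = planted["source_seq"]
            transcripts[tid] = planted["target_seq"]
            kinds[tid] = kind
            classes[tid] = "noPP"
            add_reads(planted["reads"], planted["read_rows"], "event", tid, tid)
            event_rows.append({
                **planted["event_row"],
                "source_transcript": src_id,
                "target_transcript": tid,
                "trigger_five_prime": trigger_positions[j],
                "responder_read_id": f"snet{j + 1}_responder",
            })
        transcripts[src_id] = source
        kinds[src_id] = "lncRNA"
        classes[src_id] = "noPP"
        # the reciprocal trans-ping-pong event: the trans target's responder
        # acts as trigger back onto the source, whose sense reads at the
        # trigger locus are its responders
        trans_row = event_rows[1]
        event_rows.append({
            "trigger_read_id": trans_row["responder_read_id"],
            "anneal_five_prime": trans_row["trigger_five_prime"] + 9,
            "cleavage_pos": trans_row["trigger_five_prime"],
            "mismatches": cfg.transpp_mm,
            "perfect_seed": True,
            "back_target": "trans_pingpong",
            "back_target_distance": 0,
            "source_transcript": trans_row["target_transcript"],
            "target_transcript": src_id,
            "trigger_five_prime": trans_row["cleavage_pos"],
            "responder_read_id": trans_row["trigger_read_id"],
        })

    # --- plain transcripts (no piRNA production) -------------------------
    for i in range(1, cfg.n_plain_transcripts + 1):
        tid = f"plain{i}"
        transcripts[tid] = _random_dna(rng, cfg.transcript_len)
        kinds[tid] = "mRNA"
        classes[tid] = "noPP"

    # --- contaminants -----------------------------------------------------
    structural = make_structural_decoys(rng)
    te_library = make_te_decoys(rng)
    for i in range(cfg.structural_reads):
        ref = structural[rng.integers(0, len(structural))]
        length = int(rng.integers(cfg.read_len_range[0], cfg.read_len_range[1] + 1))
        length = min(length, ref.length)
        start = int(rng.integers(0, ref.length - length + 1))
        read = SmallRead(f"struct_{i}", ref.seq[start : start + length], 1)
        reads.append(read)
        read_rows.append({
            "read_id": read.id, "category": "structural", "feature_id": ref.id,
            "transcript_id": ".", "strand": "sense", "five_prime": start + 1,
            "count": 1, "length": read.length,
        })

    tids = list(transcripts)
    for i in range(cfg.background_reads):
        tid = tids[rng.integers(0, len(tids))]
        seq = transcripts[tid]
        length = int(rng.integers(cfg.read_len_range[0], cfg.read_len_range[1] + 1))
        start = int(rng.integers(0, len(seq) - length + 1))
        window = seq[start : start + length]
        if rng.random() < 0.5:
            read_seq, strand, fp = window, "sense", start + 1
        else:
            read_seq, strand, fp = revcomp(window), "antisense", start + length
        read = SmallRead(f"noise_{i}", read_seq, 1)
        reads.append(read)
        read_rows.append({
            "read_id": read.id, "category": "noise", "feature_id": ".",
            "transcript_id": tid, "strand": strand, "five_prime": fp,
            "count": 1, "length": length,
        })

    # --- genome assembly and flank producer reads ------------------------
    gap = cfg.intergenic_gap
    chrom_parts: list[str] = []
    loci: dict[str, tuple[int, int]] = {}
    pos = 0
    for tid in transcripts:
        spacer = _random_dna(rng, gap)
        chrom_parts.append(spacer)
        pos += gap
        loci[tid] = (pos + 1, pos + len(transcripts[tid]))  # 1-based inclusive
        chrom_parts.append(transcripts[tid])
        pos += len(transcripts[tid])
    chrom_parts.append(_random_dna(rng, gap))
    chrom = "".join(chrom_parts)
    genome = {cfg.chrom_name: chrom}

    flank_true: dict[str, bool] = {}
    for fam_id, members in networks:
        for tid in members:
            start, _end = loci[tid]
            for k in range(cfg.flank_reads_per_locus):
                fp0 = start - 1 - 3000 - 40 * k  # 0-based, inside the flank
                seq = chrom[fp0 : fp0 + 26]
                read = SmallRead(f"flank_{tid}_{k}", seq, cfg.flank_read_count)
                reads.append(read)
                read_rows.append({
                    "read_id": read.id, "category": "flank_unique",
                    "feature_id": fam_id, "transcript_id": tid, "strand": "+",
                    "five_prime": fp0 + 1, "count": read.count,
                    "length": read.length,
                })
            flank_true[tid] = True

    transcript_objs = [
        Transcript(
            tid, transcripts[tid], kind=kinds[tid],
            genomic_locus=(cfg.chrom_name, loci[tid][0], loci[tid][1], "+"),
        )
        for tid in transcripts
    ]
    manifest = TruthManifest(
        reads=pd.DataFrame(read_rows),
        transcript_classes=classes,
        networks=networks,
        events=pd.DataFrame(event_rows),
        flank_true=flank_true,
    )
    return SimWorld(
        config=cfg,
        genome=genome,
        transcripts=transcript_objs,
        reads=reads,
        structural_refs=structural,
        te_library=te_library,
        manifest=manifest,
    )


def write_world(world: SimWorld, outdir: str | Path) -> dict[str, Path]:
    """Write a world to disk: genome/transcripts/decoys FASTA, transcript
    BED, reads FASTQ (one record per copy), and the manifest TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "transcripts": outdir / "transcripts.fa",
        "transcripts_bed": outdir / "transcripts.bed",
        "reads": outdir / "reads.fastq",
        "structural": outdir / "structural_decoys.fa",
        "te": outdir / "te_decoys.fa",
        "manifest_reads": outdir / "manifest_reads.tsv",
        "manifest_events": outdir / "manifest_events.tsv",
        "kinds": outdir / "transcript_kinds.tsv",
    }
    write_fasta(world.genome, paths["genome"])
    write_fasta([(t.id, t.seq) for t in world.transcripts], paths["transcripts"])
    write_bed(world.transcripts, paths["transcripts_bed"])
    write_fastq(world.reads, paths["reads"])
    write_fasta([(t.id, t.seq) for t in world.structural_refs], paths["structural"])
    write_fasta([(t.id, t.seq) for t in world.te_library], paths["te"])
    world.manifest.reads.to_csv(paths["manifest_reads"], sep="\t", index=False)
    world.manifest.events.to_csv(paths["manifest_events"], sep="\t", index=False)
    pd.DataFrame(
        [(t.id, t.kind) for t in world.transcripts], columns=["transcript_id", "kind"]
    ).to_csv(paths["kinds"], sep="\t", index=False)
    return paths
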