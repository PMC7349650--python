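"""End-to-end orchestration: filter -> map -> pingpong -> trigger -> network.

Every stage is a thin call into the corresponding module; this file owns
the run configuration (all thresholds with their standard defaults), the
read-conservation accounting, and the output tables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import filtering, network, phasing, pingpong
from .io import (
    GenomeIndex,
    SENSE,
    SmallRead,
    Transcript,
    TranscriptAlignment,
    load_genome,
    load_reads,
    load_transcripts,
    map_exact,
    write_alignments,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run (defaults are the standard
    analysis parameters)."""

    reads: str = ""
    transcripts: str = ""
    genome: str = ""
    structural_refs: str | None = None
    te_library: str | None = None
    transcript_kinds: str | None = None
    transcript_loci: str | None = None
    outdir: str = "pirnet_out"
    # thresholds
    min_len: int = 24
    max_len: int = 29
    z_threshold: float = 1.96
    min_pairs: int = 30
    overlap_window: int = 24
    min_rpm: float = 3.0
    trigger_mm_min: int = 1
    trigger_mm_max: int = 5
    te_max_mm: int = 3
    flank_nt: int = 5000
    flank_min_rpm: float = 0.5
    bias_pct: float = 50.0
    trail_window: int = 1000
    min_shared: int = 1
    collapsed_pairs: bool = False
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    config: RunConfig
    reads: list[SmallRead]  # collapsed bona fide putative piRNAs
    transcripts: list[Transcript]
    alignments: list[TranscriptAlignment]
    multiplicity_by_seq: dict[str, int]
    total_genome_mapped: int
    profiles: list[pingpong.PingPongProfile]
    networks: list[network.PingPongNetwork]
    flank_ok: dict[str, bool | None]
    events: list[phasing.TriggerEvent]
    snet_graph: "object"
    conservation: dict[str, int]
    summary: dict[str, float]


def _profile_all(
    transcripts: Sequence[Transcript],
    alignments: Sequence[TranscriptAlignment],
    reads_by_id: Mapping[str, SmallRead],
    multiplicity_by_seq: Mapping[str, int],
    total_gm: int,
    te_library: Sequence[Transcript] | None,
    collapsed_pairs: bool,
) -> list[pingpong.PingPongProfile]:
    by_tid: dict[str, list[TranscriptAlignment]] = {}
    for a in alignments:
        by_tid.setdefault(a.transcript_id, []).append(a)
    return [
        pingpong.profile_transcript(
            t, by_tid.get(t.id, []), reads_by_id, multiplicity_by_seq,
            total_gm, te_library, collapsed_pairs,
        )
        for t in transcripts
    ]


def run_objects(
    raw_reads: Sequence[SmallRead],
    transcripts: Sequence[Transcript],
    genome: Mapping[str, str],
    structural_refs: Sequence[Transcript] | None = None,
    te_library: Sequence[Transcript] | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline on in-memory objects (the CLI wraps this)."""
    cfg = config or RunConfig()
    genome_index = GenomeIndex(genome)

    # -- filter stage ------------------------------------------------------
    total_in = sum(r.count for r in raw_reads)
    mult = {seq: genome_index.multiplicity(seq) for seq in {r.seq for r in raw_reads}}
    # RPM denominator: genome-mapped copies of the whole library, 0 mm,
    # established before any length selection
    total_gm = filtering.total_genome_mapped(raw_reads, mult)
    putative = filtering.select_by_length(raw_reads, cfg.min_len, cfg.max_len)
    removed_length = total_in - sum(r.count for r in putative)
    bona_fide, removed_structural = filtering.bona_fide_filter(
        putative, structural_refs
    )
    removed_struct_total = sum(removed_structural.values())
    collapsed = filtering.collapse(bona_fide)
    conservation = {
        "reads_in": total_in,
        "removed_by_length": removed_length,
        "removed_as_structural": removed_struct_total,
        "retained": sum(r.count for r in bona_fide),
        "extra_genomic": sum(r.count for r in bona_fide if mult.get(r.seq, 0) == 0),
        "collapsed_distinct": len(collapsed),
        "total_genome_mapped": total_gm,
    }
    assert (
        conservation["reads_in"]
        == conservation["removed_by_length"]
        + conservation["removed_as_structural"]
        + conservation["retained"]
    ), "read conservation violated"
    logger.info("filter stage: %s", conservation)

    # -- map stage ---------------------------------------------------------
    alignments = map_exact(collapsed, list(transcripts))
    reads_by_id = {r.id: r for r in collapsed}

    # seeded multimapper assignment over genomic placements (locus-level
    # accounting; per-transcript profiling uses all transcript alignments)
    sites_by_read = {r.id: genome_index.locate(r.seq) for r in collapsed}
    counts_by_read = {r.id: r.count for r in collapsed}
    filtering.assign_multimappers(sites_by_read, counts_by_read, cfg.rng_seed)

    # -- pingpong stage ----------------------------------------------------
    profiles = _profile_all(
        transcripts, alignments, reads_by_id, mult, total_gm,
        te_library, cfg.collapsed_pairs,
    )
    klass_by_tid = {p.transcript_id: p.klass for p in profiles}

    # -- ping-pong networks ------------------------------------------------
    by_tid: dict[str, list[TranscriptAlignment]] = {}
    for a in alignments:
        by_tid.setdefault(a.transcript_id, []).append(a)
    pp_seqs: dict[str, set[str]] = {}
    footprints: dict[str, dict[str, tuple[int, int]]] = {}
    for tid, alns in by_tid.items():
        if klass_by_tid.get(tid) != "repeatPP":
            continue
        s_ids, a_ids = pingpong.pingpong_partners(alns)
        seqs = {reads_by_id[i].seq for i in s_ids | a_ids}
        pp_seqs[tid] = seqs
        fp: dict[str, tuple[int, int]] = {}
        for a in alns:
            seq = reads_by_id[a.read_id].seq
            if seq in seqs:
                lo, hi = fp.get(seq, (a.start, a.end))
                fp[seq] = (min(lo, a.start), max(hi, a.end))
        footprints[tid] = fp
    networks_ = network.group_pingpong_networks(pp_seqs, footprints, cfg.min_shared)

    t_by_id = {t.id: t for t in transcripts}
    member_loci = {
        tid: t_by_id[tid].genomic_locus
        for net in networks_
        for tid in net.members
    }
    unique_placements = []
    for r in collapsed:
        if mult.get(r.seq, 0) == 1:
            chrom, start0, _strand = genome_index.locate(r.seq)[0]
            unique_placements.append((chrom, start0 + 1, start0 + r.length, r.count))
    flank_ok = network.flank_unique_check(
        member_loci, unique_placements, total_gm,
        {c: len(s) for c, s in genome_index.genome.items()},
        cfg.flank_nt, cfg.flank_min_rpm,
    )

    # -- trigger stage -----------------------------------------------------
    events = phasing.infer_trigger_events(
        collapsed, list(transcripts), alignments, mult, total_gm,
        min_rpm=cfg.min_rpm,
        mm_range=(cfg.trigger_mm_min, cfg.trigger_mm_max),
        trail_window=cfg.trail_window,
    )
    snet = network.build_snet_network(events)

    edge_table = network.snet_edge_table(snet)
    summary = {
        "n_transcripts": len(transcripts),
        "n_candidate_targets": len(
            phasing.candidate_targets(
                _unique_sense_rpm(alignments, reads_by_id, mult, total_gm),
                cfg.min_rpm,
            )
        ),
        "n_significant_pp": sum(p.significant for p in profiles),
        "n_uniquePP": sum(p.klass == "uniquePP" for p in profiles),
        "n_repeatPP": sum(p.klass == "repeatPP" for p in profiles),
        "n_pingpong_networks": len(networks_),
        "n_network_transcripts": sum(len(n.members) for n in networks_),
        "n_flank_confirmed": sum(1 for v in flank_ok.values() if v),
        "n_trigger_events": len(events),
        "n_trans_pingpong_links": int(
            (edge_table["kind"] == "trans_pingpong").sum()
        ),
        "n_one_way_links": int((edge_table["kind"] == "one_way").sum()),
        "n_perfect_seed_events": sum(e.perfect_seed for e in events),
    }
    return PipelineResult(
        config=cfg, reads=collapsed, transcripts=list(transcripts),
        alignments=alignments, multiplicity_by_seq=mult,
        total_genome_mapped=total_gm, profiles=profiles, networks=networks_,
        flank_ok=flank_ok, events=events, snet_graph=snet,
        conservation=conservation, summary=summary,
    )


def _unique_sense_rpm(alignments, reads_by_id, mult, total_gm):
    acc: dict[str, int] = {}
    for a in alignments:
        if a.strand == SENSE:
            r = reads_by_id[a.read_id]
            if mult.get(r.seq, 0) == 1:
                acc[a.transcript_id] = acc.get(a.transcript_id, 0) + r.count
    return {tid: filtering.rpm(c, total_gm) for tid, c in acc.items()}


def run(config: RunConfig) -> PipelineResult:
    """Load the configured inputs, run every stage, write all outputs."""
    for key in ("reads", "transcripts", "genome"):
        path = getattr(config, key)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"config error: missing {key} path {path!r}")
    kinds = {}
    if config.transcript_kinds:
        kdf = pd.read_csv(config.transcript_kinds, sep="\t")
        kinds = dict(zip(kdf["transcript_id"], kdf["kind"]))
    raw_reads = load_reads(config.reads)
    transcripts = load_transcripts(
        config.transcripts, kinds=kinds, loci_path=config.transcript_loci
    )
    genome = load_genome(config.genome)
    structural = (
        load_transcripts(config.structural_refs) if config.structural_refs else None
    )
    te_library = (
        load_transcripts(config.te_library) if config.te_library else None
    )
    result = run_objects(
        raw_reads, transcripts, genome, structural, te_library, config
    )
    write_outputs(result, Path(config.outdir))
    return result


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(outdir / "resolved_config.yaml")
    write_alignments(result.alignments, outdir / "alignments.tsv")
    pingpong.profiles_to_frame(result.profiles).to_csv(
        outdir / "pingpong_profiles.tsv", sep="\t", index=False
    )
    phasing.events_to_frame(result.events).to_csv(
        outdir / "trigger_events.tsv", sep="\t", index=False
    )
    net_rows = [
        {
            "network_id": n.network_id,
            "members": ",".join(n.members),
            "n_members": len(n.members),
            "n_shared_reads": len(n.shared_seqs),
            "span_min_nt": n.span_range[0],
            "span_max_nt": n.span_range[1],
        }
        for n in result.networks
    ]
    pd.DataFrame(
        net_rows,
        columns=["network_id", "members", "n_members", "n_shared_reads",
                 "span_min_nt", "span_max_nt"],
    ).to_csv(outdir / "pingpong_networks.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"transcript_id": t, "flank_unique_ok": v} for t, v in result.flank_ok.items()]
    ).to_csv(outdir / "flank_check.tsv", sep="\t", index=False)
    network.write_snet_network(
        result.snet_graph, outdir / "snet_network.tsv",
        outdir / "snet_network.graphml",
    )
    # BED of trigger annealing sites on their targets (0-based half-open)
    with open(outdir / "anneal_sites.bed", "w") as fh:
        for e in result.events:
            s = e.anneal_site
            fh.write(
                f"{s.transcript_id}\t{s.start - 1}\t{s.end}\t{e.event_id}\t"
                f"{s.mismatches}\t-\n"
            )
    report = {
        "conservation": result.conservation,
        "summary": result.summary,
    }
    with open(outdir / "report.yaml", "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)
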