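"""Transcript network assembly.

Two kinds of networks are built:

* **Ping-pong networks** — undirected groups of transcripts targeted by the
  same ensemble of ping-pong piRNAs.  Two transcripts are connected when
  they share at least ``min_shared`` identical ping-pong read sequences
  (the shared reads trace a repeat common to the group, typically a few
  hundred to ~1100 nt); connected components of size >= 2 are the networks.

* **snetDNA networks** — directed graphs of trigger events: an edge
  source -> target per event, labelled ``one_way``, or ``trans_pingpong``
  when the responders target back the trigger locus (reciprocal edges are
  merged into a single trans-ping-pong link).

Producer-locus verification: a network transcript locus is accepted as a
genuine piRNA source when genome-unique reads within the locus plus/minus a
5-kb flank exceed 0.5 RPM (strictly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .phasing import TriggerEvent


@dataclass
class PingPongNetwork:
    """One shared-repeat component."""

    network_id: str
    members: tuple[str, ...]
    shared_seqs: tuple[str, ...]
    # per-member footprint (start, end) of the shared reads, 1-based
    footprints: dict[str, tuple[int, int]]

    @property
    def span_range(self) -> tuple[int, int]:
        """(min, max) footprint span across members, in nt."""
        spans = [e - s + 1 for s, e in self.footprints.values()]
        return (min(spans), max(spans)) if spans else (0, 0)


def group_pingpong_networks(
    pp_seqs_by_transcript: Mapping[str, set[str]],
    footprints_by_transcript: Mapping[str, Mapping[str, tuple[int, int]]] | None = None,
    min_shared: int = 1,
) -> list[PingPongNetwork]:
    """Group transcripts targeted by the same ensemble of ping-pong piRNAs.

    ``pp_seqs_by_transcript`` maps transcript id -> set of ping-pong-partner
    read sequences; ``footprints_by_transcript`` optionally maps transcript
    id -> {read seq -> (start, end)} for span reporting.  Components of a
    single transcript are not reported as networks.  Grouping is invariant
    to input order (nodes and members are sorted).
    """
    graph = nx.Graph()
    tids = sorted(pp_seqs_by_transcript)
    graph.add_nodes_from(tids)
    for i, a in enumerate(tids):
        for b in tids[i + 1:]:
            shared = pp_seqs_by_transcript[a] & pp_seqs_by_transcript[b]
            if len(shared) >= min_shared:
                graph.add_edge(a, b, shared=shared)
    networks = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph) if len(c) >= 2),
        key=lambda c: c[0],
    )
    for n, members in enumerate(components, start=1):
        shared: set[str] = set()
        for a, b, data in graph.subgraph(members).edges(data=True):
            shared |= data["shared"]
        footprints = {}
        if footprints_by_transcript:
            for tid in members:
                fps = [
                    footprints_by_transcript.get(tid, {}).get(s)
                    for s in shared
                ]
                fps = [fp for fp in fps if fp]
                if fps:
                    footprints[tid] = (
                        min(s for s, _ in fps), max(e for _, e in fps)
                    )
        networks.append(
            PingPongNetwork(
                network_id=f"ppnet_{n}",
                members=tuple(members),
                shared_seqs=tuple(sorted(shared)),
                footprints=footprints,
            )
        )
    return networks


def flank_unique_check(
    loci: Mapping[str, tuple[str, int, int, str] | None],
    unique_placements: Iterable[tuple[str, int, int, int]],
    total_genome_mapped: int,
    genome_lengths: Mapping[str, int],
    flank_nt: int = 5000,
    min_rpm: float = 0.5,
) -> dict[str, bool | None]:
    """Per-locus producer check: genome-unique read RPM within the locus
    plus/minus ``flank_nt`` is strictly above ``min_rpm``.

    ``unique_placements`` are (chrom, start_1based, end_1based, copies) of
    genome-unique reads.  Flanks are truncated at contig edges.  A locus
    without genomic coordinates yields None (with the caller warned via the
    returned value).
    """
    from .filtering import rpm

    placements = list(unique_placements)
    result: dict[str, bool | None] = {}
    for tid, locus in loci.items():
        if locus is None:
            result[tid] = None
            continue
        chrom, start, end, _strand = locus
        lo = max(1, start - flank_nt)
        hi = min(genome_lengths.get(chrom, end + flank_nt), end + flank_nt)
        copies = sum(
            c for (pc, ps, pe, c) in placements
            if pc == chrom and ps <= hi and pe >= lo
        )
        result[tid] = rpm(copies, total_genome_mapped) > min_rpm
    return result


def build_snet_network(events: Sequence[TriggerEvent]) -> nx.DiGraph:
    """Directed snetDNA network from classified trigger events.

    One edge per (source, target) pair, annotated with the contributing
    event ids and summed trigger/responder RPM.  An edge is labelled
    ``trans_pingpong`` when any contributing event back-targets the trigger
    locus or when the reverse edge exists (the reciprocal pair then forms a
    single trans-ping-pong link, recorded on both directions with a shared
    ``pair`` key); otherwise ``one_way``.  Nodes carry their percentage
    shares of total trigger- and responder-RPM.
    """
    graph = nx.DiGraph()
    for e in events:
        graph.add_node(e.source_transcript)
        graph.add_node(e.target_transcript)
        u, v = e.source_transcript, e.target_transcript
        if graph.has_edge(u, v):
            data = graph.edges[u, v]
            data["events"].append(e.event_id)
            data["trigger_rpm"] += e.trigger_rpm
            data["responder_rpm"] += e.responder_rpm
            if e.back_target.kind == "trans_pingpong":
                data["kind"] = "trans_pingpong"
        else:
            graph.add_edge(
                u, v,
                kind=(
                    "trans_pingpong"
                    if e.back_target.kind == "trans_pingpong"
                    else "one_way"
                ),
                events=[e.event_id],
                trigger_rpm=e.trigger_rpm,
                responder_rpm=e.responder_rpm,
            )
    # reciprocal pairs are trans-ping-pong by construction
    for u, v in list(graph.edges):
        if graph.has_edge(v, u):
            graph.edges[u, v]["kind"] = "trans_pingpong"
            graph.edges[v, u]["kind"] = "trans_pingpong"
            pair = tuple(sorted((u, v)))
            graph.edges[u, v]["pair"] = pair
            graph.edges[v, u]["pair"] = pair
    total_trig = sum(d["trigger_rpm"] for _, _, d in graph.edges(data=True))
    total_resp = sum(d["responder_rpm"] for _, _, d in graph.edges(data=True))
    for node in graph.nodes:
        trig = sum(d["trigger_rpm"] for _, _, d in graph.out_edges(node, data=True))
        resp = sum(d["responder_rpm"] for _, _, d in graph.in_edges(node, data=True))
        graph.nodes[node]["pct_trigger_rpm"] = (
            100.0 * trig / total_trig if total_trig else 0.0
        )
        graph.nodes[node]["pct_responder_rpm"] = (
            100.0 * resp / total_resp if total_resp else 0.0
        )
    return graph


def snet_edge_table(graph: nx.DiGraph) -> pd.DataFrame:
    """Edge list of the snetDNA network; reciprocal trans-ping-pong pairs are
    collapsed into one row."""
    rows = []
    seen_pairs: set[tuple[str, str]] = set()
    for u, v, data in sorted(graph.edges(data=True)):
        pair = data.get("pair")
        if pair:
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
        rows.append({
            "source": u,
            "target": v,
            "kind": data["kind"],
            "n_events": len(data["events"]),
            "events": ",".join(data["events"]),
            "trigger_rpm": data["trigger_rpm"],
            "responder_rpm": data["responder_rpm"],
        })
    return pd.DataFrame(
        rows,
        columns=["source", "target", "kind", "n_events", "events",
                 "trigger_rpm", "responder_rpm"],
    )


def write_snet_network(graph: nx.DiGraph, tsv_path, graphml_path=None) -> None:
    """Serialize the snetDNA network: edge-list TSV plus GraphML for viewers."""
    snet_edge_table(graph).to_csv(tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        g = graph.copy()
        for _, _, data in g.edges(data=True):
            data["events"] = ",".join(data["events"])
            if "pair" in data:
                data["pair"] = "|".join(data["pair"])
        nx.write_graphml(g, graphml_path)
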