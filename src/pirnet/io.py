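"""Sequence data model, format I/O, and the exact / mismatch-tolerant
search primitives used by every downstream stage.

Coordinate conventions
----------------------
Transcript coordinates are 1-based inclusive throughout the pipeline.  For a
read aligned *sense* to a transcript, ``five_prime`` is the lowest covered
coordinate; for an *antisense* read it is the highest covered coordinate
(the biological 5' end of the read sits at the downstream edge of the
covered window).  BED output is 0-based half-open; GFF3 input is read as
1-based inclusive.

The mismatch model is substitutions-only (Hamming distance), with no indels;
N never matches anything.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import (
    find_exact,
    hamming_profile,
    normalize_seq,
    revcomp,
    seq_to_array,
    window_mismatch_offsets,
)

logger = logging.getLogger(__name__)

SENSE = "sense"
ANTISENSE = "antisense"

ALIGNMENT_FORMAT_VERSION = "pirnet-alignments-v1"
_ALIGNMENT_COLUMNS = [
    "read_id",
    "transcript_id",
    "strand",
    "five_prime",
    "length",
    "mismatches",
    "mismatch_positions",
]


@dataclass(frozen=True)
class SmallRead:
    """One sequenced small RNA.

    ``count`` is the number of copies in the non-collapsed library;
    collapsed libraries hold pairwise-distinct sequences with summed counts.
    """

    id: str
    seq: str
    count: int = 1

    def __post_init__(self):
        if self.count < 1:
            raise ValueError(f"read {self.id}: count must be >= 1, got {self.count}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Transcript:
    """A transcript sequence, optionally anchored to a genomic locus.

    ``genomic_locus`` is (chrom, start, end, strand), 1-based inclusive.
    """

    id: str
    seq: str
    kind: str = "mRNA"  # {mRNA, lncRNA, unannotated}
    genomic_locus: tuple[str, int, int, str] | None = None

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"transcript {self.id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TranscriptAlignment:
    """Placement of a read on a transcript.

    ``five_prime`` is the 1-based transcript coordinate of the read's 5'
    nucleotide (lowest covered coordinate for sense, highest for antisense).
    ``mismatch_positions`` are 1-based query coordinates (1 = query 5' nt).
    """

    read_id: str
    transcript_id: str
    strand: str
    five_prime: int
    length: int
    mismatches: int = 0
    mismatch_positions: tuple[int, ...] = ()

    @property
    def start(self) -> int:
        """Lowest covered transcript coordinate (1-based)."""
        if self.strand == SENSE:
            return self.five_prime
        return self.five_prime - self.length + 1

    @property
    def end(self) -> int:
        """Highest covered transcript coordinate (1-based)."""
        if self.strand == SENSE:
            return self.five_prime + self.length - 1
        return self.five_prime

    @property
    def three_prime(self) -> int:
        """1-based transcript coordinate of the read's 3' nucleotide."""
        return self.end if self.strand == SENSE else self.start


# ---------------------------------------------------------------------------
# Loading


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    return "fasta"


def load_reads(path: str | Path, format: str | None = None) -> list[SmallRead]:
    """Load small-RNA reads from FASTA or FASTQ, one SmallRead per record.

    Every record gets count=1 (the non-collapsed library); sequences are
    uppercased and U is converted to T.  A record with an empty sequence
    raises a parse error naming the record.
    """
    fmt = _infer_format(path, format)
    reads: list[SmallRead] = []
    for i, rec in enumerate(SeqIO.parse(str(path), fmt), start=1):
        seq = normalize_seq(str(rec.seq))
        if not seq:
            raise ValueError(f"{path}: record {i} ({rec.id!r}) has no sequence")
        reads.append(SmallRead(id=rec.id, seq=seq, count=1))
    if not reads:
        warnings.warn(f"{path}: no reads parsed (empty file?)", stacklevel=2)
    return reads


def load_transcripts(
    path: str | Path,
    kinds: Mapping[str, str] | None = None,
    loci_path: str | Path | None = None,
) -> list[Transcript]:
    """Load transcripts from FASTA; optional kind map and BED6/GFF3 loci."""
    loci = read_transcript_loci(loci_path) if loci_path else {}
    transcripts = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate transcript id {rec.id!r}")
        seen.add(rec.id)
        transcripts.append(
            Transcript(
                id=rec.id,
                seq=normalize_seq(str(rec.seq)),
                kind=(kinds or {}).get(rec.id, "mRNA"),
                genomic_locus=loci.get(rec.id),
            )
        )
    return transcripts


def load_genome(path: str | Path) -> dict[str, str]:
    """Genome FASTA as a dict chrom -> uppercase sequence."""
    return {rec.id: normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def read_transcript_loci(path: str | Path) -> dict[str, tuple[str, int, int, str]]:
    """Transcript genomic loci from BED6 (0-based half-open) or GFF3
    (1-based inclusive), keyed by transcript id; returned 1-based inclusive."""
    path = Path(path)
    loci: dict[str, tuple[str, int, int, str]] = {}
    if path.suffix.lower() in {".gff", ".gff3"}:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "source", "type", "start", "end", "score", "strand",
                   "frame", "attributes"],
        )
        for row in df.itertuples():
            attrs = dict(
                kv.split("=", 1) for kv in str(row.attributes).split(";") if "=" in kv
            )
            name = attrs.get("ID") or attrs.get("Name")
            if name:
                loci[name] = (row.chrom, int(row.start), int(row.end), row.strand)
    else:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        for row in df.itertuples():
            loci[row.name] = (row.chrom, int(row.start) + 1, int(row.end), row.strand)
    return loci


# ---------------------------------------------------------------------------
# Exact mapping


def map_exact(
    reads: Iterable[SmallRead],
    transcripts: Sequence[Transcript],
    orientation: str = "both",
) -> list[TranscriptAlignment]:
    """Every exact (0-mismatch) occurrence of each read on the transcripts,
    sense and antisense.

    A read occurring at several sites yields several alignment records.
    Reads containing N are skipped and logged (they cannot match exactly).
    """
    if orientation != "both":
        raise ValueError("only orientation='both' is supported")
    alignments: list[TranscriptAlignment] = []
    # cache hits per distinct sequence so duplicate reads cost one scan
    cache: dict[str, list[tuple[str, str, int, int]]] = {}
    for read in reads:
        if "N" in read.seq:
            logger.info("map_exact: skipping read %s (contains N)", read.id)
            continue
        hits = cache.get(read.seq)
        if hits is None:
            hits = []
            rc = revcomp(read.seq)
            L = len(read.seq)
            for t in transcripts:
                for start0 in find_exact(t.seq, read.seq):
                    hits.append((t.id, SENSE, start0 + 1, L))
                for start0 in find_exact(t.seq, rc):
                    hits.append((t.id, ANTISENSE, start0 + L, L))
            cache[read.seq] = hits
        for tid, strand, five_prime, L in hits:
            alignments.append(
                TranscriptAlignment(
                    read_id=read.id, transcript_id=tid, strand=strand,
                    five_prime=five_prime, length=L, mismatches=0,
                )
            )
    return alignments


# ---------------------------------------------------------------------------
# Mismatch-tolerant reverse-complement search


def search_rc_mismatched(
    query_reads: Iterable[SmallRead],
    target_transcripts: Sequence[Transcript],
    min_mm: int,
    max_mm: int,
) -> list[TranscriptAlignment]:
    """All target windows whose Hamming distance to the reverse-complemented
    query lies in [min_mm, max_mm]; ungapped comparison at every offset.

    Hits are antisense annealing sites: ``five_prime`` is the target
    coordinate opposite the query's 5' nucleotide (the highest covered
    coordinate) and ``mismatch_positions`` are 1-based query coordinates.
    Queries shorter than 10 nt are rejected (cannot define slicing geometry).
    """
    query_reads = list(query_reads)
    for q in query_reads:
        if q.length < 10:
            raise ValueError(
                f"query {q.id}: length {q.length} < 10 nt, cannot define "
                "slicing geometry"
            )
        if not (0 <= min_mm <= max_mm <= q.length - 1):
            raise ValueError(
                f"query {q.id}: need 0 <= min_mm <= max_mm <= length-1, got "
                f"[{min_mm}, {max_mm}] for length {q.length}"
            )
    target_arrays = [(t, seq_to_array(t.seq)) for t in target_transcripts]
    sites: list[TranscriptAlignment] = []
    for q in query_reads:
        rc_arr = seq_to_array(revcomp(q.seq))
        L = q.length
        for t, t_arr in target_arrays:
            profile = hamming_profile(t_arr, rc_arr)
            for start0 in np.nonzero((profile >= min_mm) & (profile <= max_mm))[0]:
                offs = window_mismatch_offsets(t_arr, rc_arr, int(start0))
                # rc index j corresponds to query position L - j (1-based)
                qpos = tuple(sorted(int(L - j) for j in offs))
                sites.append(
                    TranscriptAlignment(
                        read_id=q.id, transcript_id=t.id, strand=ANTISENSE,
                        five_prime=int(start0) + L, length=L,
                        mismatches=int(profile[start0]),
                        mismatch_positions=qpos,
                    )
                )
    return sites


# ---------------------------------------------------------------------------
# Genome multiplicity


class GenomeIndex:
    """Exact-occurrence lookup over a genome, both strands.

    A read with multiplicity 1 is "genome-unique"; multiplicity 0 marks an
    extra-genomic read (kept for transcript-only analyses but flagged).
    """

    def __init__(self, genome: Mapping[str, str]):
        self.genome = dict(genome)
        self._cache: dict[str, list[tuple[str, int, str]]] = {}

    def locate(self, seq: str) -> list[tuple[str, int, str]]:
        """All (chrom, start0, strand) exact placements of seq, both strands."""
        hits = self._cache.get(seq)
        if hits is None:
            hits = []
            rc = revcomp(seq)
            for chrom, chrom_seq in self.genome.items():
                hits.extend((chrom, s, "+") for s in find_exact(chrom_seq, seq))
                hits.extend((chrom, s, "-") for s in find_exact(chrom_seq, rc))
            self._cache[seq] = hits
        return hits

    def multiplicity(self, seq: str) -> int:
        return len(self.locate(seq))


def genome_multiplicity(
    reads: Iterable[SmallRead], genome: Mapping[str, str] | GenomeIndex
) -> dict[str, int]:
    """Exact genomic occurrence count (both strands) per distinct read sequence."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    return {seq: index.multiplicity(seq) for seq in {r.seq for r in reads}}


# ---------------------------------------------------------------------------
# Alignment table round-trip


def write_alignments(alignments: Iterable[TranscriptAlignment], path: str | Path) -> None:
    """Write alignments as TSV with a version header; round-trips all fields."""
    rows = [
        {
            "read_id": a.read_id,
            "transcript_id": a.transcript_id,
            "strand": a.strand,
            "five_prime": a.five_prime,
            "length": a.length,
            "mismatches": a.mismatches,
            "mismatch_positions": ",".join(map(str, a.mismatch_positions)) or ".",
        }
        for a in alignments
    ]
    df = pd.DataFrame(rows, columns=_ALIGNMENT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"#{ALIGNMENT_FORMAT_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_alignments(path: str | Path) -> list[TranscriptAlignment]:
    """Read a TSV written by :func:`write_alignments`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if header != f"#{ALIGNMENT_FORMAT_VERSION}":
            raise ValueError(
                f"{path}: expected header '#{ALIGNMENT_FORMAT_VERSION}', got {header!r}"
            )
        df = pd.read_csv(fh, sep="\t", dtype={"mismatch_positions": str})
    missing = [c for c in _ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    alignments = []
    for row in df.itertuples():
        mp = () if row.mismatch_positions in (".", "", None) else tuple(
            int(x) for x in str(row.mismatch_positions).split(",")
        )
        alignments.append(
            TranscriptAlignment(
                read_id=row.read_id, transcript_id=row.transcript_id,
                strand=row.strand, five_prime=int(row.five_prime),
                length=int(row.length), mismatches=int(row.mismatches),
                mismatch_positions=mp,
            )
        )
    return alignments


# ---------------------------------------------------------------------------
# FASTA/FASTQ/BED writers (used by the simulator and CLI)


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def write_fastq(reads: Iterable[SmallRead], path: str | Path) -> None:
    """Emit the non-collapsed library: one FASTQ record per read copy."""
    with open(path, "w") as fh:
        for read in reads:
            for i in range(read.count):
                rid = read.id if read.count == 1 else f"{read.id}/{i + 1}"
                fh.write(f"@{rid}\n{read.seq}\n+\n{'I' * read.length}\n")


def write_bed(transcripts: Iterable[Transcript], path: str | Path) -> None:
    """BED6 of transcript genomic loci (0-based half-open)."""
    with open(path, "w") as fh:
        for t in transcripts:
            if t.genomic_locus is None:
                continue
            chrom, start, end, strand = t.genomic_locus
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{t.id}\t0\t{strand}\n")
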