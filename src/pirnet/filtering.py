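"""Production of the analysis read set: size selection, bona fide
filtering against structural RNAs, collapsing, multiplicity, RPM
normalization, and seeded random assignment of multimapping reads.

The RPM denominator is the total number of genome-mapped reads at zero
mismatches of the whole library (before length selection); every
transcript-level RPM in the pipeline uses this single denominator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import revcomp
from .io import SmallRead, Transcript

logger = logging.getLogger(__name__)

STRUCTURAL_CLASSES = ("miRNA", "rRNA", "snRNA", "tRNA")


@dataclass
class LibrarySummary:
    """Headline accounting for one small-RNA library."""

    total_reads: int
    total_genome_mapped: int  # 0-mm genome mappers; the RPM denominator
    bona_fide_count: int
    collapsed_count: int

    @property
    def multiplicity(self) -> float:
        """Ratio of the non-collapsed read count over the collapsed count."""
        if self.collapsed_count == 0:
            return float("nan")
        return self.bona_fide_count / self.collapsed_count


def select_by_length(
    reads: Iterable[SmallRead], min_len: int = 24, max_len: int = 29
) -> list[SmallRead]:
    """Putative piRNAs: reads with min_len <= length <= max_len (default 24-29 nt)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in reads if min_len <= r.length <= max_len]


def _structural_class(ref_id: str) -> str:
    for cls in STRUCTURAL_CLASSES:
        if cls.lower() in ref_id.lower():
            return cls
    return "structural"


def bona_fide_filter(
    reads: Iterable[SmallRead],
    structural_refs: Sequence[Transcript] | None,
) -> tuple[list[SmallRead], dict[str, int]]:
    """Remove reads matching miRNA/rRNA/snRNA/tRNA references exactly
    (0 mismatches, either orientation).

    Returns (bona fide reads, removal counts per structural class, in read
    copies). With no reference set, all reads pass with a prominent warning.
    """
    reads = list(reads)
    if not structural_refs:
        warnings.warn(
            "no structural-RNA reference set supplied: bona fide filter is a "
            "pass-through; putative piRNAs may include miRNA/rRNA/snRNA/tRNA "
            "fragments",
            stacklevel=2,
        )
        return reads, {}
    refs = [(t, revcomp(t.seq)) for t in structural_refs]
    kept: list[SmallRead] = []
    removed: dict[str, int] = {}
    for read in reads:
        hit_class = None
        for ref, ref_rc in refs:
            if read.seq in ref.seq or read.seq in ref_rc:
                hit_class = _structural_class(ref.id)
                break
        if hit_class is None:
            kept.append(read)
        else:
            removed[hit_class] = removed.get(hit_class, 0) + read.count
            logger.info("bona_fide_filter: removed %s (%s)", read.id, hit_class)
    return kept, removed


def collapse(reads: Iterable[SmallRead]) -> list[SmallRead]:
    """One record per distinct sequence with summed copy counts.

    The total copy count is preserved; record order follows first occurrence
    and ids are taken from the first read carrying each sequence.
    """
    by_seq: dict[str, SmallRead] = {}
    for read in reads:
        prev = by_seq.get(read.seq)
        if prev is None:
            by_seq[read.seq] = read
        else:
            by_seq[read.seq] = SmallRead(
                id=prev.id, seq=prev.seq, count=prev.count + read.count
            )
    return list(by_seq.values())


def library_multiplicity(reads: Iterable[SmallRead]) -> float:
    """Non-collapsed over collapsed count for a library."""
    reads = list(reads)
    collapsed = collapse(reads)
    if not collapsed:
        return float("nan")
    return sum(r.count for r in reads) / len(collapsed)


def rpm(count: float, total_genome_mapped: int) -> float:
    """Reads per million genome-mapped reads (0 mismatches)."""
    if total_genome_mapped <= 0:
        raise ValueError(
            "total_genome_mapped must be > 0: run genome mapping first to "
            "establish the RPM denominator"
        )
    return count * 1e6 / total_genome_mapped


def total_genome_mapped(
    reads: Iterable[SmallRead], multiplicity_by_seq: Mapping[str, int]
) -> int:
    """RPM denominator: summed copies of reads with >=1 exact genomic hit."""
    return sum(r.count for r in reads if multiplicity_by_seq.get(r.seq, 0) >= 1)


def assign_multimappers(
    sites_by_read: Mapping[str, Sequence],
    counts_by_read: Mapping[str, int],
    seed: int,
) -> tuple[dict[str, dict[int, int]], list[str]]:
    """Assign each read copy uniformly at random among its mapped sites.

    Returns (read_id -> {site index -> copies}, unmapped read ids).
    Genome-unique reads always go to their single site; the assignment is
    deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    assigned: dict[str, dict[int, int]] = {}
    unmapped: list[str] = []
    for read_id in sorted(sites_by_read):
        sites = sites_by_read[read_id]
        n_copies = counts_by_read[read_id]
        if len(sites) == 0:
            unmapped.append(read_id)
            continue
        if len(sites) == 1:
            assigned[read_id] = {0: n_copies}
            continue
        draw = rng.multinomial(n_copies, np.full(len(sites), 1.0 / len(sites)))
        assigned[read_id] = {i: int(n) for i, n in enumerate(draw) if n > 0}
    return assigned, unmapped
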