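"""Per-transcript ping-pong signature statistics.

The ping-pong signature of piRNA amplification is an enrichment of
sense/antisense read pairs whose 5' ends overlap by exactly 10 nt (the
PIWI slicer cuts its target between nucleotides 10 and 11 of the guide).
For each transcript we build the histogram of 5'-overlap lengths d = 1..24
over all opposite-strand read pairs, score bin 10 with a z-score against
the 24-bin background (bin 10 included), and call significance when
z > 1.96 with at least 30 overlapping pairs in the window.  The 24-nt
ceiling is the largest overlap possible for every read in the 24-29 nt
class, which keeps the background bins comparable.

Overlap direction: d = antisense_5' - sense_5' + 1; pairs with the
antisense 5' upstream of the sense 5' (negative d) are not counted,
consistent with slicer geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import hamming_profile, revcomp, seq_to_array
from .io import ANTISENSE, SENSE, GenomeIndex, SmallRead, Transcript, TranscriptAlignment

D_MAX = 24  # overlap window 1..24 nt
Z_THRESHOLD = 1.96
MIN_PAIRS = 30
UNIQUE_PP_PCT = 95.0  # > 95% genome-unique ping-pong reads -> uniquePP
BIAS_PCT = 50.0  # strict >50% for 1U / 10A bias flags


def fiveprime_counts(
    alignments: Iterable[TranscriptAlignment],
    weights: Mapping[str, int] | None = None,
) -> tuple[dict[int, float], dict[int, float]]:
    """Read weight per 5' position, split by strand, for one transcript.

    ``weights`` maps read_id -> copy count (non-collapsed counting); with
    None every alignment weighs 1 (collapsed counting).
    """
    sense: dict[int, float] = {}
    antisense: dict[int, float] = {}
    for a in alignments:
        w = 1 if weights is None else weights.get(a.read_id, 1)
        hist = sense if a.strand == SENSE else antisense
        hist[a.five_prime] = hist.get(a.five_prime, 0) + w
    return sense, antisense


def overlap_pair_counts(
    sense_5p: Mapping[int, float],
    antisense_5p: Mapping[int, float],
    d_max: int = D_MAX,
) -> np.ndarray:
    """Histogram counts[d], d = 1..d_max, of 5'-overlap lengths over all
    sense/antisense pairs: counts[d] = sum_p s(p) * a(p + d - 1)."""
    counts = np.zeros(d_max, dtype=float)
    for p, s in sense_5p.items():
        for d in range(1, d_max + 1):
            a = antisense_5p.get(p + d - 1)
            if a:
                counts[d - 1] += s * a
    return counts


def pingpong_z(counts: np.ndarray, signal_bin: int = 10) -> tuple[float, bool]:
    """z-score of the signal bin against all bins (population sd, signal bin
    included in the background).

    Returns (z, degenerate); when the bins have zero spread the z-score is
    undefined and the profile is flagged degenerate (never significant).
    """
    counts = np.asarray(counts, dtype=float)
    mean = counts.mean()
    sd = counts.std()  # population sd
    if sd == 0:
        # no spread: all-equal bins score 0 (the signal bin equals the
        # mean); all-empty bins have no defined score at all
        return (0.0 if mean > 0 else float("nan")), True
    return float((counts[signal_bin - 1] - mean) / sd), False


def call_significance(z10: float, total_pairs: float) -> bool:
    """Significant ping-pong: z > 1.96 (strict) and >= 30 overlapping pairs."""
    return bool(not math.isnan(z10) and z10 > Z_THRESHOLD and total_pairs >= MIN_PAIRS)


def base_signature(
    reads: Iterable[SmallRead], weighted: bool = True
) -> tuple[float, float]:
    """(pct1U, pct10A): percentage of reads with T at position 1 and A at
    position 10 (DNA alphabet; U is stored as T).

    ``weighted=True`` counts read copies (non-collapsed library);
    ``weighted=False`` counts distinct sequences (collapsed).  Empty input
    gives (nan, nan).
    """
    total = n1u = n10a = 0.0
    for r in reads:
        w = r.count if weighted else 1
        total += w
        if r.seq[0] == "T":
            n1u += w
        if r.length >= 10 and r.seq[9] == "A":
            n10a += w
    if total == 0:
        return float("nan"), float("nan")
    return 100.0 * n1u / total, 100.0 * n10a / total


def is_biased(pct: float) -> bool:
    """Bias flag at strict >50%; exactly 50% is not biased."""
    return bool(not math.isnan(pct) and pct > BIAS_PCT)


def pingpong_partners(
    alignments: Sequence[TranscriptAlignment],
) -> tuple[set[str], set[str]]:
    """Read ids having at least one opposite-strand read at exactly 10-nt
    5'-overlap on this transcript; returned as (sense ids, antisense ids)."""
    sense_by_pos: dict[int, list[str]] = {}
    anti_by_pos: dict[int, list[str]] = {}
    for a in alignments:
        d = sense_by_pos if a.strand == SENSE else anti_by_pos
        d.setdefault(a.five_prime, []).append(a.read_id)
    sense_ids: set[str] = set()
    anti_ids: set[str] = set()
    for p, ids in sense_by_pos.items():
        partners = anti_by_pos.get(p + 9)
        if partners:
            sense_ids.update(ids)
            anti_ids.update(partners)
    return sense_ids, anti_ids


def matches_te(seq: str, te_arrays: Sequence[np.ndarray], max_mm: int = 3) -> bool:
    """Ungapped match of a read to any TE sequence at <= max_mm mismatches,
    either orientation."""
    for arr in (seq_to_array(seq), seq_to_array(revcomp(seq))):
        for te_arr in te_arrays:
            profile = hamming_profile(te_arr, arr)
            if profile.size and profile.min() <= max_mm:
                return True
    return False


def te_and_repeat_attribution(
    pp_reads: Sequence[SmallRead],
    te_library: Sequence[Transcript] | None,
    multiplicity_by_seq: Mapping[str, int],
    max_mm: int = 3,
) -> tuple[float, float]:
    """(pct_pp_te, pct_pp_repeat) among ping-pong reads, in read copies.

    pct_pp_te is the share matching any TE at <= 3 mismatches (NaN without a
    TE library); pct_pp_repeat is the share with genome multiplicity >= 2.
    """
    total = sum(r.count for r in pp_reads)
    if total == 0:
        return float("nan"), float("nan")
    pct_repeat = 100.0 * sum(
        r.count for r in pp_reads if multiplicity_by_seq.get(r.seq, 0) >= 2
    ) / total
    if te_library is None:
        return float("nan"), pct_repeat
    te_arrays = [seq_to_array(t.seq) for t in te_library]
    pct_te = 100.0 * sum(
        r.count for r in pp_reads if matches_te(r.seq, te_arrays, max_mm)
    ) / total
    return pct_te, pct_repeat


def classify_transcript(significant: bool, pct_unique_pp: float) -> str:
    """noPP without significant ping-pong; else uniquePP when >95% of the
    ping-pong reads are genome-unique, repeatPP otherwise."""
    if not significant:
        return "noPP"
    if not math.isnan(pct_unique_pp) and pct_unique_pp > UNIQUE_PP_PCT:
        return "uniquePP"
    return "repeatPP"


def trans_pingpong_scan(
    transcript: Transcript,
    sense_5p: Mapping[int, float],
    external_reads: Sequence[SmallRead],
    max_mm: int = 5,
) -> list[TranscriptAlignment]:
    """Mismatched external partners completing a 10-nt 5'-overlap.

    Scans genome-unique piRNAs from other loci against the transcript in a
    reverse-complementary manner (up to ``max_mm`` mismatches) and keeps
    annealing sites whose 5' stands at d = 10 from a sense read's 5' on the
    transcript; these are candidate trans-ping-pong partners to compare with
    the intrinsic (0-mismatch) partners.
    """
    from .io import search_rc_mismatched  # local import to avoid cycle noise

    if not external_reads:
        return []
    sites = search_rc_mismatched(external_reads, [transcript], 0, max_mm)
    return [s for s in sites if sense_5p.get(s.five_prime - 9)]


@dataclass
class PingPongProfile:
    """Per-transcript ping-pong summary (one row of the profiles table)."""

    transcript_id: str
    z10: float
    degenerate: bool
    total_pairs: float
    significant: bool
    pct_overlap10: float
    # genome-unique-read restricted signature (UZ / UpctPP)
    z10_unique: float
    pct_overlap10_unique: float
    # base composition, sense/antisense x non-collapsed/collapsed
    pct1U_sense_nc: float
    pct10A_sense_nc: float
    pct1U_antisense_nc: float
    pct10A_antisense_nc: float
    pct1U_sense_coll: float
    pct10A_sense_coll: float
    pct1U_antisense_coll: float
    pct10A_antisense_coll: float
    sense_rpm: float
    antisense_rpm: float
    log_ratio_sense_antisense: float
    pct_unique: float
    pct_repeated: float
    pct_pp_partner_sense: float
    pct_pp_partner_antisense: float
    pct_pp_te: float
    pct_pp_repeat: float
    klass: str = "noPP"


def log_ratio_sense_antisense(sense_rpm: float, antisense_rpm: float) -> float:
    """log10 of sense/antisense bona fide RPM with a 0.06 pseudo-count on
    whichever side is zero; NaN when both are zero."""
    bs, bas = sense_rpm, antisense_rpm
    if bs == 0 and bas == 0:
        return float("nan")
    if bs == 0:
        ratio = (bs + 0.06) / bas
    elif bas == 0:
        ratio = bs / (bas + 0.06)
    else:
        ratio = bs / bas
    return math.log10(ratio)


def profile_transcript(
    transcript: Transcript,
    alignments: Sequence[TranscriptAlignment],
    reads_by_id: Mapping[str, SmallRead],
    multiplicity_by_seq: Mapping[str, int],
    total_genome_mapped: int,
    te_library: Sequence[Transcript] | None = None,
    collapsed_pairs: bool = False,
) -> PingPongProfile:
    """Full ping-pong profile for one transcript from its 0-mm alignments.

    Pair counting uses read copies by default (``collapsed_pairs=True``
    switches to distinct sequences); the two modes are never silently mixed.
    """
    weights = None if collapsed_pairs else {
        rid: reads_by_id[rid].count for rid in {a.read_id for a in alignments}
    }
    sense_5p, anti_5p = fiveprime_counts(alignments, weights)
    counts = overlap_pair_counts(sense_5p, anti_5p)
    z10, degenerate = pingpong_z(counts)
    total_pairs = float(counts.sum())
    significant = (not degenerate) and call_significance(z10, total_pairs)
    pct10 = 100.0 * counts[9] / total_pairs if total_pairs else float("nan")

    def _reads(strand: str) -> list[SmallRead]:
        seen: dict[str, SmallRead] = {}
        for a in alignments:
            if a.strand == strand:
                seen.setdefault(a.read_id, reads_by_id[a.read_id])
        return list(seen.values())

    sense_reads, anti_reads = _reads(SENSE), _reads(ANTISENSE)

    # genome-unique restriction (UZ / UpctPP)
    uniq_aln = [
        a for a in alignments
        if multiplicity_by_seq.get(reads_by_id[a.read_id].seq, 0) == 1
    ]
    u_sense, u_anti = fiveprime_counts(
        uniq_aln,
        None if collapsed_pairs else {
            rid: reads_by_id[rid].count for rid in {a.read_id for a in uniq_aln}
        },
    )
    u_counts = overlap_pair_counts(u_sense, u_anti)
    z10_u, _ = pingpong_z(u_counts)
    u_total = float(u_counts.sum())
    pct10_u = 100.0 * u_counts[9] / u_total if u_total else float("nan")

    p1u_s_nc, p10a_s_nc = base_signature(sense_reads, weighted=True)
    p1u_a_nc, p10a_a_nc = base_signature(anti_reads, weighted=True)
    p1u_s_c, p10a_s_c = base_signature(sense_reads, weighted=False)
    p1u_a_c, p10a_a_c = base_signature(anti_reads, weighted=False)

    from .filtering import rpm

    sense_rpm = rpm(sum(r.count for r in sense_reads), total_genome_mapped)
    anti_rpm = rpm(sum(r.count for r in anti_reads), total_genome_mapped)

    all_reads = {r.id: r for r in sense_reads + anti_reads}
    total_copies = sum(r.count for r in all_reads.values())
    n_unique = sum(
        r.count for r in all_reads.values()
        if multiplicity_by_seq.get(r.seq, 0) == 1
    )
    n_repeated = sum(
        r.count for r in all_reads.values()
        if multiplicity_by_seq.get(r.seq, 0) >= 2
    )
    pct_unique = 100.0 * n_unique / total_copies if total_copies else float("nan")
    pct_repeated = 100.0 * n_repeated / total_copies if total_copies else float("nan")

    pp_sense_ids, pp_anti_ids = pingpong_partners(alignments)
    sense_copies = sum(r.count for r in sense_reads)
    anti_copies = sum(r.count for r in anti_reads)
    pp_sense_copies = sum(reads_by_id[i].count for i in pp_sense_ids)
    pp_anti_copies = sum(reads_by_id[i].count for i in pp_anti_ids)
    pct_pp_s = 100.0 * pp_sense_copies / sense_copies if sense_copies else float("nan")
    pct_pp_a = 100.0 * pp_anti_copies / anti_copies if anti_copies else float("nan")

    pp_reads = [reads_by_id[i] for i in sorted(pp_sense_ids | pp_anti_ids)]
    pct_pp_te, pct_pp_repeat = te_and_repeat_attribution(
        pp_reads, te_library, multiplicity_by_seq
    )
    pp_copies = sum(r.count for r in pp_reads)
    pct_unique_pp = (
        100.0 * sum(
            r.count for r in pp_reads if multiplicity_by_seq.get(r.seq, 0) == 1
        ) / pp_copies
        if pp_copies
        else float("nan")
    )
    klass = classify_transcript(significant, pct_unique_pp)

    return PingPongProfile(
        transcript_id=transcript.id,
        z10=z10, degenerate=degenerate, total_pairs=total_pairs,
        significant=significant, pct_overlap10=pct10,
        z10_unique=z10_u, pct_overlap10_unique=pct10_u,
        pct1U_sense_nc=p1u_s_nc, pct10A_sense_nc=p10a_s_nc,
        pct1U_antisense_nc=p1u_a_nc, pct10A_antisense_nc=p10a_a_nc,
        pct1U_sense_coll=p1u_s_c, pct10A_sense_coll=p10a_s_c,
        pct1U_antisense_coll=p1u_a_c, pct10A_antisense_coll=p10a_a_c,
        sense_rpm=sense_rpm, antisense_rpm=anti_rpm,
        log_ratio_sense_antisense=log_ratio_sense_antisense(sense_rpm, anti_rpm),
        pct_unique=pct_unique, pct_repeated=pct_repeated,
        pct_pp_partner_sense=pct_pp_s, pct_pp_partner_antisense=pct_pp_a,
        pct_pp_te=pct_pp_te, pct_pp_repeat=pct_pp_repeat,
        klass=klass,
    )


# Column names align with the variables used for downstream multivariate
# summaries of these profiles (BZ/BpctPP = bona fide z and % 10-nt overlap,
# UZ/UpctPP = same on genome-unique reads, LOGratioBsBas, pctrepeats).
PROFILE_TSV_COLUMNS = {
    "z10": "BZ",
    "pct_overlap10": "BpctPP",
    "z10_unique": "UZ",
    "pct_overlap10_unique": "UpctPP",
    "log_ratio_sense_antisense": "LOGratioBsBas",
    "pct_repeated": "pctrepeats",
}


def profiles_to_frame(profiles: Sequence[PingPongProfile]):
    """Profiles as a pandas DataFrame with field-standard column aliases."""
    import pandas as pd
    from dataclasses import asdict, fields

    df = pd.DataFrame([asdict(p) for p in profiles])
    if df.empty:
        df = pd.DataFrame(columns=[f.name for f in fields(PingPongProfile)])
    return df.rename(columns=PROFILE_TSV_COLUMNS)
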