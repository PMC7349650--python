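# Methods

## Data model and conventions

Transcript coordinates are 1-based inclusive everywhere in the library; BED
output is 0-based half-open. For a sense alignment `five_prime` is the
lowest covered coordinate, for an antisense alignment the highest (the
read's biological 5′ end). All mismatch comparisons are ungapped Hamming
distances — the piRNA/target duplexes modelled here are treated as
substitution-only, with no indels. `N` never matches anything, including
another `N`; reads containing `N` are skipped by the exact mapper.

Exact transcript mapping reports *every* occurrence of a read, both
orientations, by a complete string scan (correctness over speed; at the
scales this package targets — thousands of distinct reads against
megabase-scale sequence — the C-level substring scan is not a bottleneck).
The mismatch-tolerant reverse-complement search evaluates every offset with
a vectorized window comparison; an anchor-seeded search cannot be lossless
for ≤ 5 mismatches on 24–29 nt queries (the pigeonhole anchor would be
≤ 4 nt), so no heuristic is used. Read-mapping tools based on FM-indexes
can differ from a complete scan in multi-hit reporting; the complete scan
is the reference behaviour here.

## Read filtering and normalization

Putative piRNAs are reads of 24–29 nt. Bona fide reads are those with no
exact (0-mismatch) match, in either orientation, to any structural-RNA
reference (miRNA/rRNA/snRNA/tRNA); exact matching is the minimal
reproducible choice for this filter and is deliberately conservative — a
config hook exists if a mismatch tolerance is wanted. Collapsing reduces
identical sequences to one record with summed copy counts; library
multiplicity is the non-collapsed/collapsed ratio.

RPM is reads per million genome-mapped reads at 0 mismatches, with a single
denominator per library established **before** length selection; every
transcript-level RPM uses it. Reads with genome multiplicity 0 are retained
for transcript-level analyses but flagged (transcript-only matches must
survive, e.g. reads from unannotated RNAs absent from the assembly).

Multi-mapping reads are assigned uniformly at random among their genomic
placements once per run, under the run's single seed, and the assignment is
used for locus-level accounting. Per-transcript ping-pong profiling counts
**all** transcript alignments of a read instead: the signature is a
property of the read population mappable to a transcript, and splitting a
repeat-derived read's copies across family members would make each member's
pair count an artifact of the random assignment.

## Ping-pong statistics

For one transcript, `counts[d] = Σ_p s(p)·a(p+d−1)` over sense/antisense 5′
position weights, d = 1..24. The 24-nt ceiling is the largest overlap
geometrically possible for every read in the 24–29 nt class, which keeps
the background bins comparable. The signature score is
`z₁₀ = (counts[10] − mean) / sd` with the population sd over all 24 bins,
bin 10 included in the background; significance requires `z₁₀ > 1.96`
(strict) and ≥ 30 pairs in the window (inclusive). When the bins have no
spread the score is 0 for non-empty bins (the signal bin equals the mean)
and undefined for all-empty bins; both cases carry a `degenerate` flag and
are never significant. No multiple-testing correction is applied across
transcripts by default; pair counting uses read copies (non-collapsed) by
default with a switch to distinct sequences, and the two modes are never
mixed within a profile. An alternative per-position (presence rather than
pair-product) counting convention exists in the literature; the
pair-product form is implemented as the primary definition.

1U/10A percentages use strict > 50% bias flags and are reported for sense
and antisense reads on both collapsed and non-collapsed counts. Note one
geometric coupling: within an exact d = 10 pair, the sense position-10 base
and the antisense position-1 base are the same transcript nucleotide, so
their biases co-vary by construction.

Classification: not significant ⇒ `noPP`; significant with > 95%
genome-unique ping-pong reads ⇒ `uniquePP` (intrinsic ping-pong);
otherwise `repeatPP`. TE attribution counts ping-pong reads matching a TE
library at ≤ 3 mismatches, either orientation.

## Trigger events and phasing

Trigger queries are genome-unique reads mapping any transcript sense at
0 mm (their source locus is therefore unambiguous); candidate targets are
transcripts with > 3 RPM genome-unique sense piRNAs (strict). Annealing
sites are searched at 1–5 mismatches, self-source hits excluded. The
implied cleavage position is `anneal_5′ − 9`, which holds even when base
pairing only begins at trigger position 2 or 3; responders are sense 0-mm
reads starting exactly there, and an event is retained when responder RPM
exceeds 3 (strict; configurable). Responders need not be genome-unique —
both the total and the genome-unique responder RPM are reported. A read
may be responder in one event and trigger of another; no exclusivity is
imposed.

Seed profiling reports mismatch positions within trigger coordinates 2–11.
The trail profile collects head-to-tail distances `d = next_5′ − prev_3′`
(bins 1..50) over sense reads within 1000 nt downstream of the cleavage,
chains seeded at the responders, and scores bin 1 with the same z
construction as the ping-pong score. The trail window (1000 nt) and bin
ceiling (50) bound computation and cover the planted/observed trail spans;
both are configurable, and no formal trail-calling rule exists in the
literature for this statistic — outputs label `trail_z1` as a surrogate
defined by this package.

Back-targeting: each event's responders are searched
reverse-complementarily (0–5 mm) against the event's source transcript. A
hit whose implied cleavage coincides with the trigger's 5′ locus means the
responders regenerate the trigger — trans-ping-pong; any other hit is a
downstream/offset back-target reported with its signed distance (ties
broken toward the smallest absolute distance); otherwise none.

## Networks

Ping-pong networks connect `repeatPP` transcripts sharing ≥ 1 identical
ping-pong read sequence (the permissive reading of "targeted by the same
ensemble of piRNAs"; the floor is configurable upward). Components of size
1 are not networks. Per network, the footprint span of the shared reads is
reported (expected to trace repeats of roughly 130–1130 nt). The producer
check asks for > 0.5 RPM (strict) of genome-unique reads within each
member locus ± 5 kb, truncated at contig edges; enlarging the flank can
only add reads, so the check is monotone in the flank size.

The snetDNA network is a directed graph with one edge per (source, target)
pair of events; an edge is trans-ping-pong when any contributing event
back-targets the trigger locus or when the reverse edge exists, and
reciprocal pairs collapse to a single link in the edge table. Nodes carry
their percentage shares of total trigger- and responder-RPM.

## Synthetic worlds

The generator's defaults define the reference study conditions: 3 repeat
families (repeat length drawn from 130–1130 nt) of 3 member transcripts
with 40 planted d = 10 pairs inside the shared repeat (reads therefore
genome-repeated); 2 intrinsic ping-pong transcripts with 40 genome-unique
pairs; and one snetDNA network — one source emitting three genome-unique
triggers (10 copies each) against three targets, with 2–3 mismatched
annealing windows (one carrying a seed mismatch), 50-copy responders,
five 1U-biased (p = 0.9) head-to-tail trail reads per event, one
trans-ping-pong target and one back-target planted 113 nt downstream of
its trigger locus (5 mismatches over the back-annealing site). Signature
probabilities default to 0.9; transcripts are 2.5 kb, embedded in one
chromosome with 12-kb intergenic gaps (> 2× the 5-kb flank, so flank
windows never collide), and two unique flank reads per network locus
provide producer-locus evidence. Background noise and structural
contamination default to zero; both are dialable for robustness tests, and
decoy structural/TE references are generated from the same seed (random
sequences, explicitly synthetic, never real accessions).

All planting edits the transcript sequence before reads are extracted, so
every emitted read maps at 0 mm and every planted Hamming distance is
exact; transcripts are embedded in the genome after editing. The manifest
assigns every read to exactly one category and enumerates the expected
transcript classes, network memberships and events — including the
reciprocal trans-ping-pong event, in which the trans target's responder
acts as trigger back onto the source and the source's trigger reads are
its responders.

What the generator does **not** emulate: sequencing error, adapters,
quality variation, realistic TE phylogenies, splicing, or expression-level
read-count distributions. Passing recovery tests therefore demonstrates
the correctness of the inference logic under the stated geometry, not
robustness to the full noise structure of real libraries.

## Problem sizes and numerics

The reference world holds 17 transcripts (~42 kb of transcript sequence in
a ~260-kb genome) and ~1460 read copies over ~440 distinct sequences; a
full pipeline run takes a few seconds on one core, and the test suite and
acceptance script use this scale throughout. Null calibration uses 250
transcripts with 50 + 50 uniformly placed 5′ ends on 500 nt — enough reads
that the ≥ 30-pair floor is typically met, so the z-threshold itself is
what is being calibrated (observed false-positive rate ~3–4% against the
2.5% one-sided normal nominal; the assertion allows the binomial envelope
of 5%). All randomness flows from a single integer seed; reruns are
byte-identical.

## Known limitations

* The exact scan reports all placements; aligner-based pipelines that
  report one placement per read will produce smaller per-transcript counts
  for repeated sequences.
* The trail statistic is a surrogate; no attempt is made to segment trail
  chains probabilistically or to model 3′-end heterogeneity.
* Back-target classification reports a single best hit per event; multiple
  back-annealing sites on one source are collapsed to the closest.
* PIWI-protein assignment (Aub- vs Ago3-class loading) and binding-energy
  modelling are out of scope; 1U/10A biases are reported descriptively.
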