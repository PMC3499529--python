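# Methods

This note documents the models, parameter choices and known limitations of
`mirseed`, stage by stage.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing

A read survives iff its **mean** Phred score is ≥ `min_q` (default 13,
inclusive) and it contains no `N`.  Vendor pipelines report a single
per-read quality and do not specify per-base semantics; the mean is the
least destructive per-read reading, and the threshold is configurable.

Adapter trimming takes the insert before the **leftmost** exact occurrence
of the 3′ adapter, falling back to an adapter *prefix* of ≥ `min_overlap`
(default 7) bases at the read's 3′ end; reads with no adapter evidence or
an empty insert are discarded as insert-less.  A 5′ adapter is off by
default (libraries are usually trimmed upstream) but a suffix match of the
same minimum overlap is removed when one is configured.

Inserts of 18–25 nt are collapsed to unique sequences with redundant
counts; the accounting report partitions *all* inserts
(below/in-window/above) and tabulates per-length redundant and unique
counts.  Report percentages round half-up — integers for the accounting
table, two decimals elsewhere — so regenerated reports diff textually
against printed tables.  Arithmetic behind AMFE/MFEI is done in decimal:
100·(−68.60)/160 is exactly −42.875 and must round to −42.88, which binary
floats get wrong.

## Small-RNA categorization

Reference matching is exact, full-length, both strands — consistent with
the zero-mismatch criterion used for conserved miRNAs; aligner mismatch
tolerance is deliberately not emulated.  Every read gets exactly one
category by the precedence miRNA > rRNA > tRNA > snRNA > snoRNA > mtRNA >
cpRNA > other, so category counts always sum to the library size; the
precedence order is a package choice (it is the only order under which the
published category percentages are additive).  The index precomputes all
reference substrings in the queryable length range; its equivalence to a
naive scan is tested.

## Conserved miRNA matching

A read is a conserved miRNA iff byte-identical (after T/U normalization)
to a known mature sequence — same length, zero mismatches.  Family keys
strip species prefixes and paralog/arm suffixes (`ptc-miR396e-3p` →
`miR396`).  A read matching entries in several families contributes to
each family's profile; the global miRNA read total counts it once.  This
attribution rule is a documented package choice, since published summary
counts do not specify multi-family handling.

## Folding model

A deliberately small nearest-neighbor model, self-consistent rather than
thermodynamically calibrated:

* 16-entry Watson–Crick stacking table (kcal/mol, Turner-like magnitudes);
  any stack containing a G·U pair scores a flat −0.5;
* hairpin loops: 4.0 + 0.25·(loop size), minimum loop 3;
* bulge/internal loops: 2.0 + 0.4·size, capped at 30 nt (larger interior
  loops are disallowed);
* multibranch loops: flat 3.4 closing penalty;
* lonely pairs allowed; no dangles, coaxial stacking or temperature
  dependence; pseudoknots and suboptimal structures out of scope.

The O(n³) dynamic program (numba-compiled; windows 10–2000 nt) returns one
optimal structure with a deterministic tie-break preferring the 5′-most
pairing.  Correctness rests on two independent routes, both tested: the
returned structure re-scored by a loop-decomposition walker equals the DP
energy to 1e-9, and for sequences ≤ 18 nt the DP minimum equals exhaustive
enumeration over every legal structure, exactly.

Published MFE values originate from external engines with unrecoverable
parameter sets, so no attempt is made to match them numerically: AMFE
(100·MFE/length) and MFEI (AMFE/GC%, GC as a percentage, e.g. 54.64 — the
convention under which −56.91/54.64 = −1.04) take MFE as input.  One
bundled published row (eun-MIR482-1) is internally inconsistent in print
(its AMFE does not follow from its printed length and MFE, while its MFEI
does follow from its printed AMFE, implying a length typo); the identity
checks treat it accordingly.

## Precursor discovery

Reads map to contigs by exact full-length occurrence on both strands
(every multi-mapping site reported).  Overlapping alignments chain into
blocks; chains longer than `max_block_span` (30 nt — wide enough for
isomiR wobble, narrow enough to keep mature and star apart) are split at
the deepest coverage minimum.  Two blocks with an inner gap ≤ 700 nt get a
joint window padded by 20 nt; blocks without a partner get a symmetric
120-nt window so a precursor whose star arm was never sequenced can still
be found.  Windows covering more than two blocks are rejected (the
anchoring pattern is one or two blocks).  Each window is folded at up to
three widths (+0/+30/+60 nt each side) and the minimum-MFEI structure that
passes validation is kept — published precursors range from 81 to 1545 nt,
so no single width fits.

Validation of a folded window requires, for the dominant read of each
block: no self-pairing; all pairing partners on one side (the read sits on
an arm, not across the terminal loop — two-block windows must anchor
opposite arms); a pairing fraction ≥ 0.6 into a compact partner region
(≤ read length + 8 nt); and a duplex meeting the plant miRNA annotation
convention — at most 4 unpaired read bases and no asymmetric bulge over
2 nt, evaluated on the maximal bulge-consistent pairing chain so a single
stray MFE pair at a duplex edge does not veto an otherwise perfect duplex.
The window's best-supported arm must carry ≥ 3 redundant reads: every
published dominant arm has at least that, and it is what makes scattered
single-copy background reads on decoy contigs unable to anchor a locus.
A star is considered sequenced (star-validated) when a read occupies the
partner interval within ±2 nt of the canonical Dicer 2-nt 3′-overhang
geometry.  All knobs live in `DiscoveryConfig`.

Candidates whose dominant mature equals a known mature are conserved (the
family from the reference name); the rest are novel, numbered in discovery
order, with sense/antisense candidates of one contig region grouped as two
members of one family.  Families with ≥ 2 loci get `-1`, `-2`, …
suffixes; single loci keep the bare `MIR`/`nMIR` name; reports add `s`/`a`
contig suffixes when both strands of a contig carry loci.

## Target scoring

The plant-standard penalty scheme on a 0–5 scale: mismatch 1.0, G:U 0.5,
gap 2.0 per position, doubled at seed positions 2–13; at most one bulge
per duplex (a second gap with seed doubling already exceeds the scale);
hits kept at expectation ≤ 4.0, minimal-score site per locus.
Translation inhibition is called when a mismatch or gap faces central
position 10 or 11 (G:U still permits cleavage); both the central window
and the penalties are configurable.  Only unigenes strictly longer than
600 nt are searched.  The exact parameterization of the historical web
tools is unrecoverable; these documented defaults reproduce the published
scale semantics, including score 0 → cleavage.

## Synthetic data: what it emulates, and what it does not

The generator plants hairpin precursors on contigs: star arm = reverse
complement of the mature with a chosen number of substitutions, 2-nt
spacers flanking the loop giving the duplex the canonical 2-nt 3′
overhangs (total length 2·L + loop + 4 + 2·flank).  The default scenario
— the study conditions for recovery tests — is 20 planted precursors
(10 conserved drawn from a generated miRBase-like reference, 10 novel),
mature lengths concentrated at 21 nt (the dominant redundant length in
plant leaf libraries), mature counts log-uniform 50–5000 with stars
0.5–5% of the mature (mirroring the strong mature/star asymmetry of
published read counts), 200 decoy contigs of 150–600 nt (assembled-contig
scale), 600 background reads (half from decoys, half from the
noncoding/organellar reference sets, lengths uniform 18–25 nt), reads
emitted as insert + Illumina small-RNA 3′ adapter padded to 50 nt (raw
read length before trimming is not knowable from published methods; 50 nt
is a free parameter), and an exactly-flagged 10% low-quality fraction.

What passing recovery tests shows: the mapping→blocks→windows→fold→
validate→classify chain is internally consistent and separates planted
duplex-backed hairpins from shuffled/random decoys with scattered
single-copy reads.  What it does not show: performance on real libraries
— no sequencing errors, PCR duplication, isomiR clouds, repeat-induced
multi-mapping, or assembly artifacts are simulated, and real false-positive
rates will be higher than on dinucleotide-matched decoys.

Planted hairpins are recovered on both strands (a perfect duplex is its
own reverse complement's duplex): the pipeline reports both as distinct
loci, matching the published treatment of sense/antisense precursor pairs.

## Numerical and degenerate-input choices

Ties in collapsing and dominant-read selection break by count, then
5′-most position, then lexicographic sequence, making every report
order-deterministic.  Empty libraries, windows under 10 nt, and folds with
no legal pair (MFE 0) are handled explicitly; `mfe > 0` is rejected in
statistics.  Seeds: every random choice flows from a single integer seed
per scenario/library; regeneration is bit-identical.

## Problem sizes

Default test and acceptance runs use the 20-precursor/200-decoy scenario
(~20k raw reads) and 500-sequence folding oracles; these sizes exercise
every code path while keeping the full suite under a minute of compute
plus the recovery scenario (~1–2 minutes).  All sizes are parameters.
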