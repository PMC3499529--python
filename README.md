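# mirseed

Genome-free discovery of plant microRNAs from deep-sequenced small-RNA
libraries and de novo transcriptome contigs.

Many plants of pharmacological or ecological interest — the motivating case
is *Eugenia uniflora* (pitanga, Myrtaceae) — have no sequenced genome.
miRNAs can still be discovered by combining two sequencing libraries from
the same tissue: a small-RNA library supplies the candidate mature ~21-nt
sequences and their abundances, and assembled mRNA-seq contigs stand in for
the genome as the search space for precursor hairpins.  `mirseed`
implements that analysis end to end, plus a synthetic-data generator so the
whole pipeline is testable without any external download:

1. **Preprocessing** — quality filter (mean Phred ≥ 13, no ambiguous
   bases), 3′-adapter trimming, 18–25 nt length window, collapsing to
   unique reads with redundant counts, and the library accounting report.
2. **Categorization** — exact both-strand matching against
   rRNA/tRNA/snRNA/snoRNA/mtDNA/cpDNA reference sets, one category per read
   by fixed precedence (miRNA first).
3. **Conserved miRNAs** — reads byte-identical to known mature plant
   miRNAs (complete alignment, zero mismatches), grouped into families
   (`ath-miR166a-5p` → `miR166`) with abundance profiles.
4. **Precursor discovery** — reads are mapped to contigs with perfect
   matches; one or two tight *blocks* of overlapping reads form the
   anchoring pattern; windows around the blocks are folded and accepted
   when the dominant read of each block sits on one arm of a stem with a
   compact antisense partner region on the opposite arm (the miRNA/miRNA*
   duplex, canonical 2-nt 3′ overhang for star validation).  Candidates
   are classified conserved/novel and named (`MIR827`, `MIR167-1..-4`,
   `nMIR001-1/-2` for sense/antisense pairs).
5. **Target prediction** — the mature miRNA is slid over unigenes
   (> 600 nt) scoring complementarity on the plant 0–5 penalty scale
   (mismatch 1, G:U wobble 0.5, gap 2, doubled in seed positions 2–13);
   sites with expectation ≤ 4 are reported, with cleavage vs. translation
   inhibition called from pairing at central positions 10–11.

## The statistics at the core

For a precursor of length *L* with folding energy *MFE* (kcal/mol) and GC
content *GC* (in percent):

    AMFE = 100 · MFE / L          (energy per 100 nt)
    MFEI = AMFE / GC              (minimal folding free energy index)

Strongly negative MFEI (around −1) is the classic signature separating
pre-miRNA hairpins from other transcripts.  Folding uses a built-in
simplified nearest-neighbor model (16-entry Watson–Crick stacking table,
G·U wobble stacks, affine loop penalties) whose dynamic program is proven
optimal in the test suite by exhaustive enumeration over all legal
structures of short sequences.  Because published MFE values come from
external folding engines with their own parameter sets, report arithmetic
(AMFE/MFEI) treats MFE as an input and reproduces published tables exactly.

## Worked example

```python
from mirseed import PrecursorSpec, build_precursor, fold_mfe, precursor_stats

spec = PrecursorSpec(mature_seq="TGAAGCTGCCAGCATGATCTGA", arm="5p",
                     loop_len=12, flank_len=10,
                     mature_count=616862, star_count=262)
pre, mat_off, star_off = build_precursor(spec, rng_seed=7)
fold = fold_mfe(pre)
print(fold)
print(precursor_stats(pre, fold.mfe).report())
```

prints

```
GCUAAAGACAUGAAGCUGCCAGCAUGAUCUGAAUACACGUCAGCACUCAGAUCAUGCUGGCAGCUUCAGAAUUACAUAAC
..........((((((((((((((((((((((......((....))))))))))))))))))))))))............ (-40.00)
{'length': 80, 'gc_percent': 45.0, 'mfe': -40.0, 'amfe': -50.0, 'mfei': -1.11}
```

The 22-nt mature sequence (an abundant miR167-family miRNA) pairs fully
into the star arm; the hairpin's AMFE of −50 kcal/mol per 100 nt and MFEI
of −1.11 are in the range characteristic of plant pre-miRNAs.

The whole pipeline runs from one command on a simulated study:

```sh
mirseed all --seed 5 --outdir out
```

which writes, per stage, TSV reports (library accounting, small-RNA
categories, family profiles, precursor table with
name/contig/length/GC%/MFE/AMFE/MFEI/arm reads, predicted targets), FASTA,
GFF3 and dot-bracket files, and JSON manifests with input hashes and
counts.  Two runs with the same seed are byte-identical.

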