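"""Precursor discovery: mapping, blocks, windows, validation, naming."""

import random

import pytest

from mirseed import discovery, synthetic
from mirseed.conserved import MatureReference
from mirseed.discovery import (ReadAlignment, candidate_windows,
                               discover_precursors, find_blocks, map_perfect)
from mirseed.folding import fold_mfe
from mirseed.preprocess import CollapsedRead
from mirseed.sequtils import revcomp_dna


def _aln(start, end, count=1, contig="C", strand="+", seq=None):
    seq = seq or "A" * (end - start)
    return ReadAlignment(read_seq=seq, count=count, contig_id=contig,
                         start=start, end=end, strand=strand)


class TestMapPerfect:
    def test_planted_read_found_at_ledger_coordinates(self, small_scenario,
                                                      small_library):
        truth, _, _ = small_scenario
        lib, _ = small_library
        alns = map_perfect(lib, truth.contigs)
        for p in truth.planted:
            hits = [a for a in alns if a.read_seq == p.spec.mature_seq
                    and a.contig_id == p.contig_id and a.strand == p.strand]
            assert any(a.start == p.mature_start and a.end == p.mature_end
                       for a in hits)

    def test_reverse_complement_maps_minus_strand(self):
        contig = "GGGG" + "ATCGATCGATCGATCGATCGA" + "CCCC"
        read = revcomp_dna("ATCGATCGATCGATCGATCGA")
        (a,) = map_perfect([CollapsedRead(read, 3)], {"C": contig})
        assert (a.strand, a.start, a.end) == ("-", 4, 25)
        assert contig[a.start:a.end] == revcomp_dna(read)

    def test_multi_mapping_reports_every_site(self):
        unit = "ATCGATCGATCGATCGATCGA"
        contig = unit + "TTTTTTTTTT" + unit
        alns = map_perfect([CollapsedRead(unit, 1)], {"C": contig})
        assert sorted(a.start for a in alns if a.strand == "+") == [0, 31]

    def test_order_invariance(self, small_scenario, small_library):
        truth, _, _ = small_scenario
        lib, _ = small_library
        shuffled = list(lib)
        random.Random(0).shuffle(shuffled)
        assert sorted(map_perfect(lib, truth.contigs), key=str) == \
            sorted(map_perfect(shuffled, truth.contigs), key=str)


class TestFindBlocks:
    def test_overlapping_reads_form_one_block(self):
        alns = [_aln(10 + i, 31 + i, seq="A" * 21) for i in range(4)]
        (b,) = find_blocks(alns)
        assert (b.span_start, b.span_end) == (10, 34)

    def test_distant_clusters_form_two_blocks(self):
        alns = [_aln(10, 31), _aln(110, 131)]
        blocks = find_blocks(alns)
        assert len(blocks) == 2

    def test_oversized_chain_split_at_coverage_minimum(self):
        left = [_aln(0 + i, 21 + i, count=10) for i in range(3)]
        bridge = [_aln(20, 41, count=1)]
        right = [_aln(38 + i, 59 + i, count=10) for i in range(3)]
        blocks = find_blocks(left + bridge + right, max_block_span=30)
        assert len(blocks) >= 2
        assert all(b.span_end - b.span_start <= 30 for b in blocks)

    def test_dominant_tie_break_is_five_prime_most(self):
        alns = [_aln(12, 33, count=5, seq="C" * 21),
                _aln(10, 31, count=5, seq="G" * 21)]
        (b,) = find_blocks(alns)
        assert b.dominant_read.start == 10


class TestCandidateWindows:
    def test_pair_window_arithmetic(self):
        blocks = find_blocks([_aln(100, 121), _aln(181, 202)])
        ((ws, we), wb), = candidate_windows(blocks, contig_len=400)
        assert (ws, we) == (80, 222)
        assert len(wb) == 2

    def test_three_blocks_in_window_rejected(self):
        blocks = find_blocks([_aln(100, 121), _aln(140, 161), _aln(170, 191)])
        assert candidate_windows(blocks, contig_len=400) == []

    def test_singleton_window_is_symmetric(self):
        blocks = find_blocks([_aln(300, 321)])
        ((ws, we), wb), = candidate_windows(blocks, contig_len=1000)
        assert (ws, we) == (180, 441)
        assert len(wb) == 1


def _planted_library(truth, extra=()):
    reads = {}
    for p in truth.planted:
        reads[p.spec.mature_seq] = reads.get(p.spec.mature_seq, 0) \
            + p.spec.mature_count
        if p.spec.star_count:
            reads[p.star_seq] = reads.get(p.star_seq, 0) + p.spec.star_count
    for seq, count in extra:
        reads[seq] = reads.get(seq, 0) + count
    return [CollapsedRead(s, c) for s, c in sorted(reads.items())]


class TestValidateHairpin:
    def test_planted_duplex_accepted_with_star(self, small_scenario):
        truth, _, _ = small_scenario
        lib = _planted_library(truth)
        cands = discover_precursors(lib, truth.contigs)
        for p in truth.planted:
            mine = [c for c in cands if c.contig_id == p.contig_id
                    and c.strand == p.strand]
            assert mine, f"no candidate at {p.contig_id}{p.strand}"
            assert any(c.star_validated for c in mine)

    def test_read_across_two_stems_rejected(self):
        """A read spanning the junction of two separate hairpins pairs into
        both sides and must fail the one-arm criterion."""
        stem_a = "GGGGCCCCGGGG" + "AAAA" + "CCCCGGGGCCCC"
        stem_b = "GGGGCCCCGGGG" + "TTTT" + "CCCCGGGGCCCC"
        contig = stem_a + stem_b
        read = contig[22:43]  # junction-spanning 21-mer
        fold = fold_mfe(contig)
        blocks = find_blocks([ReadAlignment(read, 10, "C", 22, 43, "+")])
        res = discovery.validate_hairpin(contig, blocks, fold,
                                         (0, len(contig)), "+")
        assert res is None

    def test_star_detection_counts_match_construction(self):
        """Novel precursors given star reads validate; those without do not
        (the 14-of-17 star-evidence pattern reproduced as a scenario shape)."""
        rng = random.Random(77)
        specs = []
        for i in range(17):
            mature = "".join(rng.choice("ACGT") for _ in range(21))
            specs.append(synthetic.PrecursorSpec(
                mature_seq=mature, arm=rng.choice(("5p", "3p")),
                loop_len=rng.randint(8, 20), flank_len=15,
                mature_count=100, star_count=5 if i < 14 else 0))
        contigs, planted = {}, []
        for i, spec in enumerate(specs):
            pre, moff, soff = synthetic.build_precursor(spec, rng_seed=i)
            cid = f"C{i:02d}"
            contigs[cid] = "ACGT" * 8 + pre + "TGCA" * 8
            L = len(spec.mature_seq)
            planted.append(synthetic.PlantedLocus(
                contig_id=cid, start=32, end=32 + len(pre), strand="+",
                spec=spec, mature_start=32 + moff, mature_end=32 + moff + L,
                star_start=32 + soff, star_end=32 + soff + L,
                star_seq=pre[soff:soff + L]))
        truth = synthetic.SyntheticTruth(
            planted=planted, decoy_contigs=[], contigs=contigs,
            references={}, mature_reference=[], seed=0)
        lib = _planted_library(truth)
        cands = discover_precursors(lib, truth.contigs)
        with_star = {c.contig_id for c in cands
                     if c.strand == "+" and c.star_validated}
        star_truth = {p.contig_id for p in planted if p.spec.star_count}
        assert with_star == star_truth


class TestClassifyAndName:
    def _candidate(self, contig, window, strand, mature, count=50):
        c = discovery.PrecursorCandidate(
            contig_id=contig, strand=strand, window=window,
            seq="A" * (window[1] - window[0]), fold=None, stats=None,
            mature_5p=(mature, count), mature_3p=None, star_validated=True,
            total_reads=count)
        return c

    def test_single_locus_family_keeps_bare_name(self):
        ref = MatureReference.from_entries([("ath-miR827", "T" * 21)])
        (c,) = discovery.classify_and_name(
            [self._candidate("C1", (0, 100), "+", "T" * 21)], ref)
        assert c.classification == "conserved"
        assert c.locus_name == "MIR827"

    def test_multi_locus_family_gets_numeric_suffixes(self):
        ref = MatureReference.from_entries([("ath-miR167a", "G" * 21)])
        cands = [self._candidate(f"C{i}", (0, 100), "+", "G" * 21)
                 for i in range(4)]
        named = discovery.classify_and_name(cands, ref)
        assert [c.locus_name for c in named] == [
            "MIR167-1", "MIR167-2", "MIR167-3", "MIR167-4"]

    def test_sense_antisense_novel_pair_shares_family(self):
        cands = [self._candidate("C9", (10, 130), "+", "A" * 21),
                 self._candidate("C9", (10, 130), "-", "C" * 21)]
        named = discovery.classify_and_name(cands, None)
        assert [c.locus_name for c in named] == ["nMIR001-1", "nMIR001-2"]
        assert all(c.classification == "novel" for c in named)


class TestEndToEnd:
    def test_long_precursor_window_contains_planted_interval(self):
        """An 820-nt planted precursor (the long-precursor regime) is
        recovered with a window covering the whole planted interval."""
        mature = "TCGGCTGTCAATTTCTGGATT"
        spec = synthetic.PrecursorSpec(
            mature_seq=mature, arm="5p", flank_len=40,
            loop_len=820 - 2 * 21 - 4 - 80, mature_count=100, star_count=4)
        pre, moff, soff = synthetic.build_precursor(spec, rng_seed=6)
        assert len(pre) == 820
        contig = "ACGT" * 20 + pre + "TGCA" * 20
        truth_reads = [CollapsedRead(mature, 100),
                       CollapsedRead(pre[soff:soff + 21], 4)]
        cands = discover_precursors(truth_reads, {"CL": contig})
        mine = [c for c in cands if c.strand == "+"]
        assert mine
        best = mine[0]
        assert best.window[0] <= 80 and best.window[1] >= 80 + 820

    def test_strand_symmetry(self, small_scenario):
        """Reverse-complementing every contig flips candidate strands and
        mirrors coordinates, nothing else."""
        truth, _, _ = small_scenario
        lib = _planted_library(truth)
        fwd = discover_precursors(lib, truth.contigs)
        flipped = {cid: revcomp_dna(s) for cid, s in truth.contigs.items()}
        rev = discover_precursors(lib, flipped)
        def key(c, contig_len):
            s, e = c.window
            return (c.contig_id, contig_len - e, contig_len - s,
                    {"+": "-", "-": "+"}[c.strand], c.seq)
        fwd_keys = {key(c, len(truth.contigs[c.contig_id])) for c in fwd}
        rev_keys = {(c.contig_id, c.window[0], c.window[1], c.strand, c.seq)
                    for c in rev}
        assert fwd_keys == rev_keys

    def test_total_reads_bounds_and_stats_identities(self, small_scenario,
                                                     small_library,
                                                     small_mature_ref):
        truth, _, _ = small_scenario
        lib, _ = small_library
        cands = discover_precursors(lib, truth.contigs, small_mature_ref)
        assert cands
        for c in cands:
            assert c.total_reads >= c.dominant_mature[1]
            rep = c.stats.report()
            assert rep["amfe"] == pytest.approx(
                100 * c.stats.mfe / c.stats.length, abs=0.01)
            assert rep["mfei"] == pytest.approx(
                rep["amfe"] / c.stats.gc_percent, abs=0.02)
            assert len(c.seq) == c.window[1] - c.window[0]
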