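"""Target scoring: penalty arithmetic, thresholding, inhibition calls."""

import random

import pytest

from mirseed.sequtils import revcomp_dna, to_rna
from mirseed.targets import (Duplex, filter_unigenes, find_targets,
                             inhibition_mode, score_duplex)

MIRNA = "TGAAGCTGCCAGCATGATCTGA"  # 22 nt


def _perfect_duplex(mirna):
    m = to_rna(mirna)
    target = "".join({"A": "U", "U": "A", "G": "C", "C": "G"}[c] for c in m)
    return Duplex(mirna=m, target=target)


def _edit(duplex, pos, kind):
    """Apply one edit facing miRNA position `pos` (1-based)."""
    m, t = list(duplex.mirna), list(duplex.target)
    i = pos - 1
    if kind == "mismatch":
        t[i] = m[i]  # same base never pairs
    elif kind == "wobble":
        # make it G:U from the miRNA side
        m[i], t[i] = "G", "U"
    elif kind == "gap":
        t[i] = "-"
    return Duplex(mirna="".join(m), target="".join(t))


class TestFilterUnigenes:
    def test_boundary_is_strict(self):
        ts = [("short", "A" * 600), ("long", "A" * 601)]
        assert filter_unigenes(ts) == [("long", "A" * 601)]

    def test_mixed_fixture_count(self):
        rng = random.Random(1)
        ts = [(f"t{i}", "A" * rng.choice((400, 550, 600, 601, 700, 900)))
              for i in range(10)]
        kept = filter_unigenes(ts)
        assert len(kept) == sum(1 for _, s in ts if len(s) > 600)


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        assert score_duplex(MIRNA, _perfect_duplex(MIRNA)) == 0.0

    def test_wobble_outside_seed(self):
        d = _edit(_perfect_duplex(MIRNA), 15, "wobble")
        assert score_duplex(d.mirna, d) == 0.5

    def test_mismatch_in_seed_doubled(self):
        d = _edit(_perfect_duplex(MIRNA), 5, "mismatch")
        assert score_duplex(MIRNA, d) == 2.0

    def test_single_edit_enumeration_matches_rule(self):
        """Every single edit at every position scores exactly the rule's
        penalty (seed positions 2-13 doubled)."""
        for pos in range(1, len(MIRNA) + 1):
            in_seed = 2 <= pos <= 13
            base = _perfect_duplex(MIRNA)
            assert score_duplex(MIRNA, _edit(base, pos, "mismatch")) == \
                (2.0 if in_seed else 1.0)
            assert score_duplex(MIRNA, _edit(base, pos, "gap")) == \
                (4.0 if in_seed else 2.0)
            m = to_rna(MIRNA)
            wob = Duplex(mirna=m, target=base.target[:pos - 1] + "U"
                         + base.target[pos:]) if m[pos - 1] == "G" else None
            if wob:
                assert score_duplex(MIRNA, wob) == (1.0 if in_seed else 0.5)

    def test_monotonicity_under_accumulating_edits(self):
        """Adding mismatches/wobbles/gaps never decreases the score."""
        rng = random.Random(42)
        for _ in range(300):
            d = _perfect_duplex(MIRNA)
            prev = 0.0
            positions = rng.sample(range(1, len(MIRNA) + 1),
                                   rng.randint(1, 6))
            for pos in positions:
                d = _edit(d, pos, rng.choice(("mismatch", "wobble", "gap")))
                s = score_duplex(d.mirna.replace("-", ""), d)
                assert s >= prev - 1e-9
                prev = s

    def test_incomplete_alignment_rejected(self):
        with pytest.raises(ValueError):
            score_duplex(MIRNA, Duplex(mirna=to_rna(MIRNA)[:-1],
                                       target="A" * 21))


class TestFindTargets:
    def test_embedded_complement_hits_with_score_zero(self):
        site = revcomp_dna(MIRNA)
        transcript = "G" * 300 + site + "C" * 320
        hits = find_targets("miR-x", MIRNA, [("t1", transcript)])
        assert len(hits) == 1
        h = hits[0]
        assert h.score == 0.0
        assert h.inhibition == "Cleavage"
        assert (h.target_start, h.target_end) == (300, 300 + len(MIRNA))

    def test_threshold_excludes_poor_sites(self):
        """No hit is reported above the expectation cutoff; a transcript
        with no complementarity yields nothing at all."""
        m = to_rna(MIRNA)
        L = len(m)
        s = [{"A": "U", "U": "A", "G": "C", "C": "G"}[c] for c in m][::-1]
        # corrupt three seed positions: penalty 6.0 > 4.0
        for pos in (3, 5, 7):
            s[L - pos] = m[pos - 1]
        transcript = "G" * 250 + "".join(s) + "C" * 250
        hits = find_targets("miR-x", MIRNA, [("t1", transcript)],
                            expectation=4.0)
        assert all(h.score <= 4.0 for h in hits)
        assert not any(h.target_start <= 250 < h.target_end for h in hits)
        assert find_targets("miR-x", "A" * 21, [("t2", "A" * 700)]) == []

    def test_planted_edit_compositions_score_as_hand_computed(self):
        """Planted sites of known edit composition score the hand-computed
        penalty sums."""
        rng = random.Random(9)
        m = to_rna(MIRNA)
        L = len(m)
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        cases = []
        for _ in range(20):
            site = [comp[c] for c in m][::-1]  # 5'->3' target site
            edits = rng.sample(range(1, L + 1), rng.randint(0, 3))
            expected = 0.0
            ok = True
            for pos in edits:
                i = L - pos  # site index facing miRNA position pos
                if m[pos - 1] == site[i]:
                    ok = False
                    break
                site[i] = m[pos - 1]  # same base = guaranteed mismatch
                expected += 2.0 if 2 <= pos <= 13 else 1.0
            if not ok or expected > 4.0:
                continue
            cases.append(("".join(site), expected))
        assert cases
        for k, (site, expected) in enumerate(cases):
            transcript = "G" * 100 + site + "C" * 100
            hits = find_targets(f"m{k}", MIRNA, [("t", transcript)])
            planted = [h for h in hits
                       if h.target_start <= 100 < h.target_end]
            assert planted and planted[0].score == expected

    def test_reverse_complement_transcript_scores_identically(self):
        """The same planted site scores equally when the transcript is
        reverse-complemented and the site annotation flipped."""
        site = revcomp_dna(MIRNA)
        fwd = "GGCC" * 30 + site + "TTAA" * 30
        hits_f = find_targets("m", MIRNA, [("t", fwd)])
        hits_r = find_targets("m", revcomp_dna(MIRNA),
                              [("t", revcomp_dna(fwd))])
        assert hits_f and hits_r
        assert min(h.score for h in hits_f) == min(h.score for h in hits_r)


class TestInhibitionMode:
    def test_perfect_duplex_is_cleavage(self):
        assert inhibition_mode(_perfect_duplex(MIRNA)) == "Cleavage"

    @pytest.mark.parametrize("pos", [10, 11])
    def test_central_mismatch_is_translation(self, pos):
        d = _edit(_perfect_duplex(MIRNA), pos, "mismatch")
        assert inhibition_mode(d) == "Translation"

    def test_peripheral_mismatch_stays_cleavage(self):
        d = _edit(_perfect_duplex(MIRNA), 18, "mismatch")
        assert inhibition_mode(d) == "Cleavage"

    def test_mixed_suite_calls_match_construction(self):
        rng = random.Random(23)
        for _ in range(100):
            d = _perfect_duplex(MIRNA)
            central_hit = False
            for pos in rng.sample(range(1, len(MIRNA) + 1),
                                  rng.randint(1, 4)):
                kind = rng.choice(("mismatch", "gap"))
                d = _edit(d, pos, kind)
                if pos in (10, 11):
                    central_hit = True
            assert inhibition_mode(d) == (
                "Translation" if central_hit else "Cleavage")
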