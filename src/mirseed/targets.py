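"""Plant miRNA target prediction on a 0-5 penalty scale.

Scores miRNA/mRNA complementarity with the standard plant-target penalty
system: each miRNA position facing a mismatch costs 1.0, a G:U wobble 0.5
and a gap (bulged base on either strand) 2.0, with penalties doubled inside
the seed region (miRNA positions 2-13 from the 5' end).  A site is reported
when its cumulative penalty is at most the expectation cutoff (default 4.0);
0 means perfect full-length complementarity.

The repression mode is called from duplex geometry: pairing across the
central positions 10-11 permits Argonaute slicing (Cleavage); a mismatch or
gap facing either central position blocks it (Translation inhibition).

Only transcripts strictly longer than the unigene length cutoff (default
600 nt) are searched, and at most one bulge per duplex is considered — a
second gap already exceeds the 0-5 scale once seed doubling applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .sequtils import to_rna

SEED_RANGE = (2, 13)        #: miRNA positions (1-based, 5'->3') with doubled penalty
CENTRAL_POSITIONS = (10, 11)  #: positions whose disruption blocks cleavage

MISMATCH = 1.0
WOBBLE = 0.5
GAP = 2.0

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class Duplex:
    """Gapped alignment of a miRNA (5'->3') against a target site (3'->5').

    Equal-length strings; '-' marks a bulge on the respective strand."""

    mirna: str
    target: str

    def __post_init__(self) -> None:
        if len(self.mirna) != len(self.target):
            raise ValueError("aligned strings must have equal length")

    def columns(self) -> Iterable[tuple[int, str, str]]:
        """Yield (miRNA position 1-based, miRNA char, target char); bulged
        target bases carry the position of the next miRNA base."""
        pos = 0
        for m, t in zip(self.mirna, self.target):
            if m != "-":
                pos += 1
            yield pos if m != "-" else pos + 1, m, t


@dataclass(frozen=True)
class TargetHit:
    mirna_name: str
    transcript_id: str
    target_start: int  # transcript coords, 0-based half-open
    target_end: int
    score: float
    inhibition: str
    duplex: Duplex


def filter_unigenes(transcripts: Sequence[tuple[str, str]],
                    min_len: int = 600) -> list[tuple[str, str]]:
    """Keep transcripts strictly longer than ``min_len`` nt."""
    return [(tid, seq) for tid, seq in transcripts if len(seq) > min_len]


def _column_penalty(pos: int, m: str, t: str,
                    seed: tuple[int, int] = SEED_RANGE) -> float:
    if m == "-" or t == "-":
        p = GAP
    elif (m, t) in _WC:
        p = 0.0
    elif (m, t) in _GU:
        p = WOBBLE
    else:
        p = MISMATCH
    if seed[0] <= pos <= seed[1]:
        p *= 2.0
    return p


def score_duplex(mirna: str, duplex: Duplex,
                 seed: tuple[int, int] = SEED_RANGE) -> float:
    """Cumulative penalty of a duplex; 0 = perfect complementarity.

    The alignment must cover the full miRNA; penalties never decrease when
    edits are added (each column's contribution is non-negative).
    """
    m_rna = to_rna(mirna)
    aln_m = duplex.mirna.replace("-", "")
    if to_rna(aln_m) != m_rna:
        raise ValueError("alignment does not cover the full miRNA")
    return sum(_column_penalty(pos, to_rna(m) if m != "-" else "-",
                               to_rna(t) if t != "-" else "-", seed)
               for pos, m, t in duplex.columns())


def inhibition_mode(duplex: Duplex,
                    central: tuple[int, ...] = CENTRAL_POSITIONS) -> str:
    """'Translation' iff a mismatch or gap faces a central position
    (G:U wobble still permits slicing), else 'Cleavage'."""
    for pos, m, t in duplex.columns():
        if pos in central:
            if m == "-" or t == "-":
                return "Translation"
            mr, tr = to_rna(m), to_rna(t)
            if (mr, tr) not in _WC and (mr, tr) not in _GU:
                return "Translation"
    return "Cleavage"


def _alignments_at(mirna_rna: str, site: str) -> Iterable[tuple[Duplex, int]]:
    """Candidate duplexes for the site starting at one transcript position.

    ``site`` is the transcript subsequence (5'->3', RNA) long enough for the
    variant; the duplex pairs miRNA position i with the site base L-1-i
    (antiparallel).  Yields (duplex, site_length_used).
    """
    L = len(mirna_rna)
    # ungapped
    if len(site) >= L:
        w = site[:L]
        yield Duplex(mirna=mirna_rna, target=w[::-1]), L
    # one bulged miRNA base (target side gap) at interior positions
    if len(site) >= L - 1:
        w = site[:L - 1]
        rev = w[::-1]
        for g in range(1, L - 1):
            yield Duplex(mirna=mirna_rna,
                         target=rev[:g] + "-" + rev[g:]), L - 1
    # one bulged target base (miRNA side gap)
    if len(site) >= L + 1:
        w = site[:L + 1]
        rev = w[::-1]
        for g in range(1, L):
            yield Duplex(mirna=mirna_rna[:g] + "-" + mirna_rna[g:],
                         target=rev), L + 1


def find_targets(mirna_name: str, mirna_seq: str,
                 transcripts: Sequence[tuple[str, str]],
                 expectation: float = 4.0,
                 seed: tuple[int, int] = SEED_RANGE,
                 central: tuple[int, ...] = CENTRAL_POSITIONS,
                 ) -> list[TargetHit]:
    """Scan transcripts for sites scoring at most ``expectation``.

    Slides the miRNA over every position allowing at most one bulge, keeps
    the minimal-score duplex per locus (overlapping hits suppressed), and
    sorts by score, then transcript id, then position.
    """
    m_rna = to_rna(mirna_seq)
    L = len(m_rna)
    raw: list[TargetHit] = []
    for tid, seq in transcripts:
        t_rna = to_rna(seq)
        for p in range(len(t_rna) - (L - 1) + 1):
            best: tuple[float, Duplex, int] | None = None
            for duplex, used in _alignments_at(m_rna, t_rna[p:p + L + 1]):
                if p + used > len(t_rna):
                    continue
                s = score_duplex(m_rna, duplex, seed)
                if best is None or s < best[0]:
                    best = (s, duplex, used)
            if best is not None and best[0] <= expectation:
                raw.append(TargetHit(
                    mirna_name=mirna_name, transcript_id=tid,
                    target_start=p, target_end=p + best[2], score=best[0],
                    inhibition=inhibition_mode(best[1], central),
                    duplex=best[1]))
    # keep minimal-score hit per locus: suppress overlaps, best first
    raw.sort(key=lambda h: (h.score, h.transcript_id, h.target_start))
    kept: list[TargetHit] = []
    for h in raw:
        if any(k.transcript_id == h.transcript_id
               and h.target_start < k.target_end and h.target_end > k.target_start
               for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (h.score, h.transcript_id, h.target_start))
    return kept


def targets_table(hits: Sequence[TargetHit]) -> pd.DataFrame:
    rows = [(h.mirna_name, h.inhibition,
             f"{h.score:g}", h.transcript_id,
             h.target_start + 1, h.target_end,
             f"{h.duplex.mirna}|{h.duplex.target}")
            for h in hits]
    return pd.DataFrame(rows, columns=[
        "miRNA", "Inhibition", "Score", "transcript", "start", "end",
        "duplex"])
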