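"""Conserved miRNA identification by exact matching to known matures.

A library read is a conserved miRNA iff it is byte-identical (after T/U
normalization) to a known mature plant miRNA — complete alignment, zero
mismatches, no length slack.  Matched reads are grouped into miRNA families
derived from miRBase-style names (``ath-miR166a-5p`` -> ``miR166``) and
summarized as per-family abundance profiles.

A read matching reference entries in different families contributes to each
family's profile, while the global miRNA read total counts it once; family
membership rules for cross-family matches are a documented package choice.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .preprocess import CollapsedRead
from .sequtils import to_dna

logger = logging.getLogger(__name__)

_NAME_RE = re.compile(r"^(?:[A-Za-z]{2,4}-)?(?:mir|miR|MIR)(\d+)", re.ASCII)


@dataclass(frozen=True)
class MatureReference:
    """Known mature miRNAs: (name, family, seq-DNA), unique sequences kept."""

    entries: tuple[tuple[str, str, str], ...]

    @classmethod
    def from_entries(cls, entries) -> "MatureReference":
        out = []
        for name, *rest in entries:
            if len(rest) == 2:
                family, seq = rest
            else:
                (seq,) = rest
                family = family_name(name)
            out.append((name, family, to_dna(seq)))
        return cls(entries=tuple(out))

    @classmethod
    def from_fasta(cls, path) -> "MatureReference":
        entries = [(rec.id, family_name(rec.id), str(rec.seq))
                   for rec in SeqIO.parse(str(path), "fasta")]
        if not entries:
            raise ValueError(f"no mature reference entries in {path}")
        return cls.from_entries(entries)

    def seq_to_names(self) -> dict[str, list[str]]:
        m: dict[str, list[str]] = {}
        for name, _, seq in self.entries:
            m.setdefault(seq, []).append(name)
        return m


def family_name(ref_name: str) -> str:
    """Canonical family key of a miRBase-style mature name.

    Strips the species prefix, lettered paralog / locus suffixes and arm
    suffixes: ``ptc-miR396e-3p`` -> ``miR396``.  Unparseable names are
    returned verbatim (and logged) so nothing is silently dropped.
    """
    if not ref_name:
        raise ValueError("empty reference name")
    m = _NAME_RE.match(ref_name)
    if not m:
        logger.warning("unparseable miRNA name %r; using it as its own family",
                       ref_name)
        return ref_name
    return f"miR{m.group(1)}"


def match_conserved(lib: list[CollapsedRead], ref: MatureReference,
                    ) -> dict[str, list[str]]:
    """Map read sequence -> matching reference names (exact, full-length)."""
    if not ref.entries:
        raise ValueError("empty mature reference")
    lookup = ref.seq_to_names()
    return {r.seq: sorted(lookup[r.seq]) for r in lib if r.seq in lookup}


@dataclass(frozen=True)
class FamilyProfile:
    """Per-family membership and abundance."""

    family: str
    members: tuple[tuple[str, int], ...]  # (seq, count), descending count

    @property
    def member_count(self) -> int:
        return len(self.members)

    @property
    def total_reads(self) -> int:
        return sum(c for _, c in self.members)

    @property
    def min_count(self) -> int:
        return min(c for _, c in self.members)

    @property
    def max_count(self) -> int:
        return max(c for _, c in self.members)


def family_profiles(matches: dict[str, list[str]],
                    lib: list[CollapsedRead]) -> list[FamilyProfile]:
    """Aggregate matched reads into family profiles.

    Members are sorted by descending count, ties lexicographic by sequence;
    profiles sorted by family name.  Input order of the library is
    irrelevant.
    """
    counts = {r.seq: r.count for r in lib}
    fam_members: dict[str, set[str]] = {}
    for seq, names in matches.items():
        for fam in {family_name(n) for n in names}:
            fam_members.setdefault(fam, set()).add(seq)
    profiles = []
    for fam in sorted(fam_members):
        members = sorted(((s, counts[s]) for s in fam_members[fam]),
                         key=lambda kv: (-kv[1], kv[0]))
        profiles.append(FamilyProfile(family=fam, members=tuple(members)))
    return profiles


def mirna_hit_seqs(matches: dict[str, list[str]]) -> set[str]:
    """Read sequences identified as conserved miRNAs (for categorization)."""
    return set(matches)


def profiles_table(profiles: list[FamilyProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.family, p.member_count, p.total_reads, p.min_count, p.max_count)
         for p in profiles],
        columns=["family", "members", "total_reads", "min_count", "max_count"])


def matches_table(matches: dict[str, list[str]],
                  lib: list[CollapsedRead]) -> pd.DataFrame:
    counts = {r.seq: r.count for r in lib}
    rows = [(seq, counts[seq], ";".join(names))
            for seq, names in sorted(matches.items(),
                                     key=lambda kv: (-counts[kv[0]], kv[0]))]
    return pd.DataFrame(rows, columns=["seq", "count", "matched_names"])
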