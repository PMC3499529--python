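"""Classify collapsed reads against noncoding/organellar reference sets.

Each 18-25 nt read is assigned exactly one category by exact, full-length,
both-strand substring matching against per-category reference FASTA sets
(rRNA, tRNA, snRNA, snoRNA, mitochondrial and chloroplast sequences), with a
fixed precedence so no read is double-counted:

    miRNA > rRNA > tRNA > snRNA > snoRNA > mtRNA > cpRNA > other

miRNA membership is decided upstream by the conserved-miRNA matcher and
passed in; "other" is the complement bucket.  Counts are redundant (weighted
by collapsed-read counts) over the in-window library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .preprocess import CollapsedRead
from .sequtils import revcomp_dna, round_half_up, to_dna

CATEGORY_PRECEDENCE = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "mtRNA", "cpRNA")


@dataclass(frozen=True)
class ReferenceSet:
    """One category's reference sequences (DNA alphabet)."""

    category: str
    sequences: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_PRECEDENCE[1:]:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.sequences:
            raise ValueError(f"empty reference set for {self.category}")
        object.__setattr__(self, "sequences",
                           tuple((sid, to_dna(s)) for sid, s in self.sequences))


class SubstringIndex:
    """Exact full-length substring lookup over reference sets, both strands.

    Precomputes every substring in the queryable length range, so a query is
    a dict lookup; equivalent to (and tested against) a naive scan.
    """

    def __init__(self, refs: list[ReferenceSet], min_len: int = 18,
                 max_len: int = 25) -> None:
        if not refs:
            raise ValueError("at least one reference set required")
        cats = [r.category for r in refs]
        if len(set(cats)) != len(cats):
            raise ValueError("duplicate reference category")
        self.min_len, self.max_len = min_len, max_len
        self._map: dict[str, set[str]] = {}
        for ref in refs:
            for _, seq in ref.sequences:
                for strand_seq in (seq, revcomp_dna(seq)):
                    for L in range(min_len, max_len + 1):
                        for i in range(len(strand_seq) - L + 1):
                            sub = strand_seq[i:i + L]
                            self._map.setdefault(sub, set()).add(ref.category)

    def query(self, read_seq: str) -> set[str]:
        """Categories whose references contain the read as an exact substring
        on either strand; empty set for no hit."""
        return self._map.get(to_dna(read_seq), set())


def build_match_index(refs: list[ReferenceSet], min_len: int = 18,
                      max_len: int = 25) -> SubstringIndex:
    return SubstringIndex(refs, min_len=min_len, max_len=max_len)


@dataclass
class CategoryReport:
    """Redundant read counts and percentages per small-RNA category."""

    counts: dict[str, int]
    denominator: int
    percentages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert sum(self.counts.values()) == self.denominator
        if not self.percentages:
            self.percentages = {
                cat: round_half_up(100 * c / self.denominator, 2) if self.denominator else 0.0
                for cat, c in self.counts.items()}

    def to_table(self) -> pd.DataFrame:
        order = list(CATEGORY_PRECEDENCE) + ["other"]
        rows = [(cat if cat != "other" else "Other sRNA",
                 self.counts.get(cat, 0),
                 f"{self.percentages.get(cat, 0.0):.2f}%")
                for cat in order]
        return pd.DataFrame(rows, columns=["Small RNA type", "Number of reads",
                                           "Percentage"])


def classify_library(lib: list[CollapsedRead], index: SubstringIndex,
                     mirna_hits: set[str]) -> CategoryReport:
    """Partition the library into categories by the fixed precedence.

    ``mirna_hits`` is the set of read sequences matched to known mature
    miRNAs on this same library; it takes precedence over every reference
    category.  Each read lands in exactly one bucket, so the counts always
    sum to the redundant library size.
    """
    counts = {cat: 0 for cat in CATEGORY_PRECEDENCE}
    counts["other"] = 0
    for read in lib:
        if read.seq in mirna_hits:
            counts["miRNA"] += read.count
            continue
        cats = index.query(read.seq)
        for cat in CATEGORY_PRECEDENCE[1:]:
            if cat in cats:
                counts[cat] += read.count
                break
        else:
            counts["other"] += read.count
    return CategoryReport(counts=counts, denominator=sum(r.count for r in lib))
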