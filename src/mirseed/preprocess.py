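"""Raw small-RNA FASTQ to a collapsed, length-filtered library.

Pipeline: drop low-quality and ambiguous reads, trim the 3' (and optionally
5') ligation adapter, keep inserts in the 18-25 nt window and collapse them
to unique sequences with redundant counts.  The accounting report partitions
every insert by length window and tabulates per-length redundant and unique
counts (the read-length distribution of the library).

The quality threshold is applied to the mean Phred score of the read: the
upstream vendor pipelines this emulates report a single per-read quality, and
mean quality is the least destructive per-read reading of such a cutoff.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .sequtils import round_half_up


@dataclass(frozen=True)
class CollapsedRead:
    """A unique small-RNA sequence with its redundant read count."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not self.seq or set(self.seq) - set("ACGT"):
            raise ValueError(f"collapsed read must be uppercase DNA: {self.seq!r}")


@dataclass
class LibrarySummary:
    """Length-window accounting over all trimmed inserts."""

    total_reads: int = 0
    in_window: int = 0
    below: int = 0
    above: int = 0
    per_length_redundant: dict[int, int] = field(default_factory=dict)
    per_length_unique: dict[int, int] = field(default_factory=dict)

    def check(self) -> None:
        assert self.total_reads == self.in_window + self.below + self.above
        assert sum(self.per_length_redundant.values()) == self.total_reads


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Stream (id, seq, qual) from plain or gzipped FASTQ; malformed records
    raise with the 1-based record index."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        it = FastqGeneralIterator(fh)
        idx = 0
        while True:
            idx += 1
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record #{idx} in {path}: {exc}") from exc
            yield title.split()[0], seq, qual


def mean_quality(qual: str) -> float:
    """Mean Sanger (+33) Phred score of a quality string."""
    if not qual:
        return 0.0
    return sum(ord(c) - 33 for c in qual) / len(qual)


def quality_filter(records: Iterable[tuple[str, str, str]],
                   min_q: int = 13) -> Iterator[tuple[str, str, str]]:
    """Keep reads with mean quality >= min_q and no ambiguous base.

    The threshold is inclusive: a read whose every base is exactly ``min_q``
    survives.  Any 'N'/'n' drops the read regardless of quality.
    """
    for rid, seq, qual in records:
        if "N" in seq or "n" in seq:
            continue
        if mean_quality(qual) < min_q:
            continue
        yield rid, seq, qual


def trim_adapter(seq: str, adapter3p: str, min_overlap: int = 7,
                 adapter5p: str = "") -> str | None:
    """Insert before the leftmost 3' adapter occurrence, or None.

    Falls back to an adapter *prefix* of length >= ``min_overlap`` at the
    read's 3' end (adapter running off the read).  Reads without any adapter
    evidence, or with an empty insert (adapter-only reads), return None.
    An optional 5' adapter: an insert beginning with a 5'-adapter suffix of
    length >= ``min_overlap`` is trimmed likewise.
    """
    if not adapter3p:
        raise ValueError("adapter3p must be non-empty")
    idx = seq.find(adapter3p)
    if idx >= 0:
        insert = seq[:idx]
    else:
        insert = None
        for k in range(len(adapter3p) - 1, min_overlap - 1, -1):
            if seq.endswith(adapter3p[:k]):
                insert = seq[:-k]
                break
        if insert is None:
            return None
    if adapter5p:
        for k in range(len(adapter5p), min_overlap - 1, -1):
            if insert.startswith(adapter5p[-k:]):
                insert = insert[k:]
                break
    return insert or None


def length_filter_and_collapse(reads: Iterable[str], lo: int = 18, hi: int = 25,
                               ) -> tuple[list[CollapsedRead], LibrarySummary]:
    """Collapse in-window inserts to unique sequences; account for all.

    Collapse conserves total in-window count and is input-order independent:
    the library is sorted by descending count, ties broken lexicographically.
    """
    counts: Counter[str] = Counter()
    summary = LibrarySummary()
    red: Counter[int] = Counter()
    uniq_sets: dict[int, set[str]] = {}
    for seq in reads:
        n = len(seq)
        summary.total_reads += 1
        red[n] += 1
        uniq_sets.setdefault(n, set()).add(seq)
        if n < lo:
            summary.below += 1
        elif n > hi:
            summary.above += 1
        else:
            summary.in_window += 1
            counts[seq] += 1
    summary.per_length_redundant = dict(sorted(red.items()))
    summary.per_length_unique = {k: len(v) for k, v in sorted(uniq_sets.items())}
    lib = [CollapsedRead(seq=s, count=c)
           for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    summary.check()
    return lib, summary


def preprocess_fastq(path, adapter3p: str, min_q: int = 13, lo: int = 18,
                     hi: int = 25, min_overlap: int = 7, adapter5p: str = "",
                     ) -> tuple[list[CollapsedRead], LibrarySummary]:
    """Full preprocessing of one FASTQ file."""
    def inserts() -> Iterator[str]:
        for _, seq, _ in quality_filter(read_fastq(path), min_q=min_q):
            ins = trim_adapter(seq, adapter3p, min_overlap=min_overlap,
                               adapter5p=adapter5p)
            if ins is not None:
                yield ins
    return length_filter_and_collapse(inserts(), lo=lo, hi=hi)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def summary_table(summary: LibrarySummary, lo: int = 18, hi: int = 25) -> pd.DataFrame:
    """Read-accounting table: total / in-window / below / above with integer
    percentages (half-up), mirroring standard sRNA library reports."""
    total = summary.total_reads
    rows = [
        ("Total reads", total, 100),
        (f"{lo}–{hi} nt", summary.in_window,
         int(round_half_up(100 * summary.in_window / total, 0)) if total else 0),
        (f"<{lo} nt", summary.below,
         int(round_half_up(100 * summary.below / total, 0)) if total else 0),
        (f">{hi} nt", summary.above,
         int(round_half_up(100 * summary.above / total, 0)) if total else 0),
    ]
    return pd.DataFrame(rows, columns=["Type", "Number of reads", "Percentage"])


def length_distribution_table(summary: LibrarySummary) -> pd.DataFrame:
    """Per-length redundant and unique counts (length-distribution figure)."""
    lengths = sorted(set(summary.per_length_redundant) | set(summary.per_length_unique))
    return pd.DataFrame({
        "length": lengths,
        "redundant": [summary.per_length_redundant.get(k, 0) for k in lengths],
        "unique": [summary.per_length_unique.get(k, 0) for k in lengths],
    })


def write_collapsed_fasta(lib: list[CollapsedRead], path) -> None:
    """Collapsed library as FASTA with ``>read{i}_x{count}`` headers."""
    with open(path, "w") as fh:
        for i, r in enumerate(lib, start=1):
            fh.write(f">read{i}_x{r.count}\n{r.seq}\n")


def read_collapsed_fasta(path) -> list[CollapsedRead]:
    lib: list[CollapsedRead] = []
    with open(path) as fh:
        name = None
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:]
            elif line and name is not None:
                count = int(name.rsplit("_x", 1)[1])
                lib.append(CollapsedRead(seq=line.upper(), count=count))
                name = None
    return lib
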