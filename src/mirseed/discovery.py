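"""Hairpin precursor discovery on transcriptome contigs.

The genome-free discovery path: collapsed reads are mapped onto contigs with
exact full-length matches on both strands; per contig strand, overlapping
alignments are chained into tight *read blocks* (the anchoring unit — a
putative mature or star position); windows around one or two blocks are
excised and folded; a window is accepted as a precursor when its minimum-
energy structure places the dominant read of each block inside the stem on
one arm, base-pairing compactly into the opposite arm, with two-block
windows anchored on opposite arms.  Accepted candidates are classified as
conserved (dominant mature identical to a known mature miRNA) or novel, and
named by family/locus conventions.

The anchoring-pattern parameters (block span, window flanks, pairing
fraction) are deliberately exposed: the field's precursor filters differ in
exactly these knobs, and the defaults here are documented choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .conserved import MatureReference, family_name
from .folding import FoldResult, PrecursorStats, fold_mfe, precursor_stats
from .preprocess import CollapsedRead
from .sequtils import revcomp_dna, to_dna


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadAlignment:
    """One exact full-length placement of a read on a contig.

    Coordinates are 0-based half-open on the forward strand; for '-' strand
    alignments ``contig[start:end] == revcomp(read_seq)``.
    """

    read_seq: str
    count: int
    contig_id: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class ReadBlock:
    """A maximal chain of overlapping alignments on one contig strand."""

    contig_id: str
    strand: str
    span_start: int
    span_end: int
    alignments: tuple[ReadAlignment, ...]

    @property
    def dominant_read(self) -> ReadAlignment:
        """Max-count alignment; ties broken 5'-most then by sequence."""
        return min(self.alignments,
                   key=lambda a: (-a.count, a.start, a.read_seq))

    @property
    def total_count(self) -> int:
        return sum(a.count for a in self.alignments)


@dataclass
class PrecursorCandidate:
    """An accepted hairpin precursor with its reads and statistics."""

    contig_id: str
    strand: str
    window: tuple[int, int]
    seq: str  # strand-oriented DNA sequence of the window
    fold: FoldResult
    stats: PrecursorStats
    mature_5p: tuple[str, int] | None
    mature_3p: tuple[str, int] | None
    star_validated: bool
    total_reads: int
    classification: str = ""   # "conserved" or "novel"
    family: str | None = None
    locus_name: str = ""

    @property
    def dominant_mature(self) -> tuple[str, int]:
        arms = [a for a in (self.mature_5p, self.mature_3p) if a is not None]
        if not arms:
            raise ValueError("candidate without a mature arm")
        return max(arms, key=lambda sc: sc[1])


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------


def map_perfect(lib: Sequence[CollapsedRead], contigs: dict[str, str],
                ) -> list[ReadAlignment]:
    """All exact full-length occurrences of each read, both strands.

    Multi-mapping reads report every site.  Implemented with a k-mer
    position index per read length, so runtime is one pass over the contigs
    per distinct length plus a dict lookup per read.
    """
    if not contigs:
        raise ValueError("no contigs to map against")
    lengths = sorted({len(r.seq) for r in lib})
    index: dict[str, list[tuple[str, int]]] = {}
    norm = {cid: to_dna(seq) for cid, seq in contigs.items()}
    wanted: set[str] = set()
    for r in lib:
        wanted.add(r.seq)
        wanted.add(revcomp_dna(r.seq))
    for cid, seq in norm.items():
        for L in lengths:
            for i in range(len(seq) - L + 1):
                sub = seq[i:i + L]
                if sub in wanted:
                    index.setdefault(sub, []).append((cid, i))
    out: list[ReadAlignment] = []
    for r in lib:
        for sub, strand in ((r.seq, "+"), (revcomp_dna(r.seq), "-")):
            for cid, i in index.get(sub, ()):
                if strand == "-" and r.seq == sub:
                    continue  # palindromic read: forward hit already recorded
                out.append(ReadAlignment(read_seq=r.seq, count=r.count,
                                         contig_id=cid, start=i,
                                         end=i + len(r.seq), strand=strand))
    out.sort(key=lambda a: (a.contig_id, a.strand, a.start, a.end, a.read_seq))
    return out


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------


def _coverage_split(chain: list[ReadAlignment]) -> tuple[list[ReadAlignment],
                                                         list[ReadAlignment]]:
    """Split an overlapping chain at its deepest coverage minimum."""
    s0 = min(a.start for a in chain)
    e0 = max(a.end for a in chain)
    cov = [0] * (e0 - s0)
    for a in chain:
        for p in range(a.start - s0, a.end - s0):
            cov[p] += a.count
    # interior minimum, excluding the first/last alignment's core
    lo = min(a.end for a in chain) - s0
    hi = max(a.start for a in chain) - s0
    if lo >= hi:  # fully nested chain; split by start order median
        mid = len(chain) // 2
        return chain[:mid], chain[mid:]
    p_min = min(range(lo, hi), key=lambda p: (cov[p], p)) + s0
    left = [a for a in chain if (min(a.end, p_min) - a.start)
            >= (a.end - max(a.start, p_min))]
    right = [a for a in chain if a not in left]
    if not left or not right:
        mid = len(chain) // 2
        return chain[:mid], chain[mid:]
    return left, right


def find_blocks(alignments: Sequence[ReadAlignment],
                max_block_span: int = 30) -> list[ReadBlock]:
    """Chain overlapping alignments per (contig, strand) into blocks.

    Chains whose span exceeds ``max_block_span`` are split recursively at
    the deepest coverage minimum, separating e.g. a mature block from an
    adjacent isomiR cloud.
    """
    groups: dict[tuple[str, str], list[ReadAlignment]] = {}
    for a in alignments:
        groups.setdefault((a.contig_id, a.strand), []).append(a)
    blocks: list[ReadBlock] = []

    def emit(chain: list[ReadAlignment]) -> None:
        span = max(a.end for a in chain) - min(a.start for a in chain)
        if span > max_block_span and len(chain) > 1:
            left, right = _coverage_split(chain)
            emit(left)
            emit(right)
            return
        blocks.append(ReadBlock(
            contig_id=chain[0].contig_id, strand=chain[0].strand,
            span_start=min(a.start for a in chain),
            span_end=max(a.end for a in chain),
            alignments=tuple(sorted(chain, key=lambda a: (a.start, a.end,
                                                          a.read_seq)))))

    for (_, _), group in sorted(groups.items()):
        group.sort(key=lambda a: (a.start, a.end))
        chain: list[ReadAlignment] = []
        cur_end = -1
        for a in group:
            if chain and a.start > cur_end:
                emit(chain)
                chain = []
            chain.append(a)
            cur_end = max(cur_end, a.end)
        if chain:
            emit(chain)
    blocks.sort(key=lambda b: (b.contig_id, b.strand, b.span_start))
    return blocks


# ---------------------------------------------------------------------------
# Candidate windows
# ---------------------------------------------------------------------------


def candidate_windows(blocks: Sequence[ReadBlock], contig_len: int,
                      flank: int = 20, max_pair_distance: int = 700,
                      singleton_flank: int = 120,
                      ) -> list[tuple[tuple[int, int], tuple[ReadBlock, ...]]]:
    """Windows around one or two anchoring blocks on one contig strand.

    Block pairs whose inner gap is within ``max_pair_distance`` get a joint
    window padded by ``flank``; blocks with no neighbor get a symmetric
    ``singleton_flank`` window (the star arm may simply lack sequenced
    reads).  Prospective windows containing more than two blocks are
    rejected: the anchoring pattern is one or two blocks.
    """
    bl = sorted(blocks, key=lambda b: b.span_start)
    if any((b.contig_id, b.strand) != (bl[0].contig_id, bl[0].strand)
           for b in bl):
        raise ValueError("candidate_windows expects blocks of one contig strand")
    windows: list[tuple[tuple[int, int], tuple[ReadBlock, ...]]] = []
    paired: set[int] = set()
    for i in range(len(bl)):
        for j in range(i + 1, len(bl)):
            gap = bl[j].span_start - bl[i].span_end
            if gap > max_pair_distance:
                break
            ws = max(0, bl[i].span_start - flank)
            we = min(contig_len, bl[j].span_end + flank)
            others = [b for k, b in enumerate(bl) if k not in (i, j)
                      and b.span_start < we and b.span_end > ws]
            if others:
                continue
            windows.append(((ws, we), (bl[i], bl[j])))
            paired.add(i)
            paired.add(j)
    for i, b in enumerate(bl):
        if i in paired:
            continue
        ws = max(0, b.span_start - singleton_flank)
        we = min(contig_len, b.span_end + singleton_flank)
        others = [x for k, x in enumerate(bl) if k != i
                  and x.span_start < we and x.span_end > ws]
        if others:
            continue
        windows.append(((ws, we), (b,)))
    windows.sort(key=lambda w: w[0])
    return windows


# ---------------------------------------------------------------------------
# Hairpin validation
# ---------------------------------------------------------------------------


def _oriented(pos: tuple[int, int], window: tuple[int, int],
              strand: str) -> tuple[int, int]:
    """Map forward-strand contig coords into strand-oriented window coords."""
    ws, we = window
    s, e = pos
    if strand == "+":
        return s - ws, e - ws
    return we - e, we - s


def _duplex_chain(by_pos: list[int | None], a0: int, a1: int,
                  max_bulge: int) -> list[tuple[int, int]]:
    """Maximal bulge-consistent pairing chain of a read within a fold.

    ``by_pos[k]`` is the partner of read base k (or None).  Returns the
    longest subsequence of (read_index, partner) whose partners lie on one
    side of the read, decrease monotonically, and whose step asymmetry
    (read gap vs partner gap) never exceeds ``max_bulge`` — the read/star
    duplex with stray MFE pairs trimmed away.
    """
    cands = [(k, p) for k, p in enumerate(by_pos)
             if p is not None and not a0 <= p < a1]
    best: list[tuple[int, int]] = []
    for side in ("L", "R"):
        pts = [(k, p) for k, p in cands
               if (p < a0) == (side == "L")]
        if not pts:
            continue
        n = len(pts)
        length = [1] * n
        prev = [-1] * n
        for j in range(n):
            for i in range(j):
                ki, pi = pts[i]
                kj, pj = pts[j]
                if pj >= pi:
                    continue
                gap_read = kj - ki - 1
                gap_star = pi - pj - 1
                if abs(gap_star - gap_read) > max_bulge:
                    continue
                if length[i] + 1 > length[j]:
                    length[j] = length[i] + 1
                    prev[j] = i
        jbest = max(range(n), key=lambda j: (length[j], -pts[j][0]))
        chain: list[tuple[int, int]] = []
        j = jbest
        while j >= 0:
            chain.append(pts[j])
            j = prev[j]
        chain.reverse()
        if len(chain) > len(best):
            best = chain
    return best


def validate_hairpin(window_seq: str, blocks: Sequence[ReadBlock],
                     fold: FoldResult, window: tuple[int, int], strand: str,
                     min_paired_frac: float = 0.6, max_duplex_slop: int = 8,
                     star_tol: int = 2, max_unpaired_mature: int = 4,
                     max_bulge: int = 2, min_read_support: int = 3,
                     ) -> dict | None:
    """Test the stem-loop criteria for one folded window.

    Accepts iff for each block's dominant read, within the fold:
    (a) all of its base-pairing partners lie on one side (the read sits on
        one arm, not across the terminal loop), two-block windows anchoring
        on opposite arms;
    (b) at least ``min_paired_frac`` of its bases pair into the opposite
        arm, and the partner positions span a compact region
        (<= read length + ``max_duplex_slop``) — the anti-sense sequence on
        the opposite arm;
    (c) none of its bases pair with another of its own bases (no self-fold);
    (d) the duplex meets the plant miRNA annotation standard: at most
        ``max_unpaired_mature`` read bases unpaired and no asymmetric bulge
        larger than ``max_bulge`` nt — random folds pair short reads
        loosely, a mature/star duplex pairs them nearly perfectly;
    and the window's best-supported arm carries at least
    ``min_read_support`` redundant reads (scattered single-copy background
    cannot anchor a locus).

    ``star_validated`` is true iff some sequenced read occupies the expected
    star interval within ``star_tol`` nt of the canonical 2-nt 3' overhang
    geometry.
    """
    n = len(window_seq)
    arms: dict[str, tuple[str, int]] = {}
    partner_sets = []
    for b in blocks:
        dom = b.dominant_read
        a0, a1 = _oriented((dom.start, dom.end), window, strand)
        if a0 < 0 or a1 > n:
            return None
        by_pos = [fold.pair_table.get(i) for i in range(a0, a1)]
        if any(p is not None and a0 <= p < a1 for p in by_pos):
            return None  # (c) self-fold
        chain = _duplex_chain(by_pos, a0, a1, max_bulge)
        if not chain:
            return None
        partners = sorted(p for _, p in chain)
        if len(chain) < min_paired_frac * (a1 - a0):
            return None  # (b) pairing fraction
        if (a1 - a0) - len(chain) > max_unpaired_mature:
            return None  # (d) too many unpaired / stray read bases
        one_side_5p = partners[0] >= a1
        if partners[-1] - partners[0] + 1 > (a1 - a0) + max_duplex_slop:
            return None  # (b) partners not a compact anti-sense region
        arm = "5p" if one_side_5p else "3p"
        if arm in arms:
            return None  # two blocks on the same arm
        seq = window_seq[a0:a1]
        arms[arm] = (seq, dom.count)
        partner_sets.append((arm, a0, a1, partners, b))

    if max(count for _, count in arms.values()) < min_read_support:
        return None

    # star check: any read placed at the canonical star interval
    star_validated = False
    all_aligns = [a for b in blocks for a in b.alignments]
    for arm, a0, a1, partners, b in partner_sets:
        exp_s, exp_e = partners[0], partners[-1] + 1
        for a in all_aligns:
            r0, r1 = _oriented((a.start, a.end), window, strand)
            if r0 >= a0 and r1 <= a1:
                continue  # the mature block itself
            if (abs(r0 - exp_s) <= star_tol and
                    abs(r1 - (exp_e + 2)) <= star_tol + 2):
                star_validated = True
            if abs(r0 - exp_s) <= star_tol and abs(r1 - exp_e) <= star_tol:
                star_validated = True
    return {
        "mature_5p": arms.get("5p"),
        "mature_3p": arms.get("3p"),
        "star_validated": star_validated,
    }


# ---------------------------------------------------------------------------
# End-to-end discovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscoveryConfig:
    max_block_span: int = 30
    flank: int = 20
    max_pair_distance: int = 700
    singleton_flank: int = 120
    min_paired_frac: float = 0.6
    max_duplex_slop: int = 8
    star_tol: int = 2
    max_unpaired_mature: int = 4
    max_bulge: int = 2
    min_read_support: int = 3
    #: symmetric window extensions tried in addition to the base window;
    #: the minimum-MFEI structure passing validation is kept
    extra_widths: tuple[int, ...] = (0, 30, 60)
    max_window: int = 2000


def discover_precursors(lib: Sequence[CollapsedRead], contigs: dict[str, str],
                        mature_ref: MatureReference | None = None,
                        config: DiscoveryConfig = DiscoveryConfig(),
                        name_prefix: str = "",
                        ) -> list[PrecursorCandidate]:
    """Full discovery: map, block, window, fold, validate, classify, name."""
    alignments = map_perfect(lib, contigs)
    blocks = find_blocks(alignments, max_block_span=config.max_block_span)
    by_cs: dict[tuple[str, str], list[ReadBlock]] = {}
    for b in blocks:
        by_cs.setdefault((b.contig_id, b.strand), []).append(b)

    # total reads per window need every alignment on the strand, not only
    # the anchoring blocks'
    aligns_by_cs: dict[tuple[str, str], list[ReadAlignment]] = {}
    for a in alignments:
        aligns_by_cs.setdefault((a.contig_id, a.strand), []).append(a)

    candidates: list[PrecursorCandidate] = []
    for (cid, strand), bl in sorted(by_cs.items()):
        contig = to_dna(contigs[cid])
        for (ws, we), wblocks in candidate_windows(
                bl, len(contig), flank=config.flank,
                max_pair_distance=config.max_pair_distance,
                singleton_flank=config.singleton_flank):
            best: PrecursorCandidate | None = None
            for ext in config.extra_widths:
                s = max(0, ws - ext)
                e = min(len(contig), we + ext)
                if e - s < 10 or e - s > config.max_window:
                    continue
                sub = contig[s:e]
                wseq = sub if strand == "+" else revcomp_dna(sub)
                fold = fold_mfe(wseq)
                if fold.mfe >= 0:
                    continue
                res = validate_hairpin(
                    wseq, wblocks, fold, (s, e), strand,
                    min_paired_frac=config.min_paired_frac,
                    max_duplex_slop=config.max_duplex_slop,
                    star_tol=config.star_tol,
                    max_unpaired_mature=config.max_unpaired_mature,
                    max_bulge=config.max_bulge,
                    min_read_support=config.min_read_support)
                if res is None:
                    continue
                stats = precursor_stats(wseq, fold.mfe)
                total = sum(a.count for a in aligns_by_cs[(cid, strand)]
                            if a.start >= s and a.end <= e)
                cand = PrecursorCandidate(
                    contig_id=cid, strand=strand, window=(s, e), seq=wseq,
                    fold=fold, stats=stats, total_reads=total, **res)
                if best is None or cand.stats.mfei < best.stats.mfei:
                    best = cand
            if best is not None:
                candidates.append(best)
    candidates.sort(key=lambda c: (c.contig_id, c.window, c.strand))
    return classify_and_name(candidates, mature_ref, prefix=name_prefix)


def classify_and_name(candidates: list[PrecursorCandidate],
                      mature_ref: MatureReference | None,
                      prefix: str = "") -> list[PrecursorCandidate]:
    """Classify conserved vs novel and assign family/locus names.

    Conserved: the dominant mature is byte-identical to a reference mature;
    family from the reference name.  Novel families are numbered in
    discovery order (``nMIR001`` ...), with sense/antisense candidates of one
    contig region grouped as members of the same family.  Families with two
    or more loci get ``-1``, ``-2`` ... suffixes; single loci keep the bare
    family name.
    """
    lookup = mature_ref.seq_to_names() if mature_ref else {}
    fam_of: list[str | None] = []
    for c in candidates:
        seq, _ = c.dominant_mature
        names = lookup.get(to_dna(seq))
        if names:
            c.classification = "conserved"
            c.family = family_name(sorted(names)[0])
        else:
            c.classification = "novel"
            c.family = None
        fam_of.append(c.family)

    # group novel candidates: same contig, overlapping windows -> one family
    novel_group: dict[int, int] = {}
    groups: list[tuple[str, int, int]] = []  # contig, start, end
    for idx, c in enumerate(candidates):
        if c.classification != "novel":
            continue
        for gi, (gcid, gs, ge) in enumerate(groups):
            if c.contig_id == gcid and c.window[0] < ge and c.window[1] > gs:
                novel_group[idx] = gi
                groups[gi] = (gcid, min(gs, c.window[0]), max(ge, c.window[1]))
                break
        else:
            novel_group[idx] = len(groups)
            groups.append((c.contig_id, c.window[0], c.window[1]))
    for idx, gi in novel_group.items():
        candidates[idx].family = f"nMIR{gi + 1:03d}"

    # locus numbering within each family, in discovery order
    by_family: dict[str, list[int]] = {}
    for idx, c in enumerate(candidates):
        by_family.setdefault(c.family, []).append(idx)
    for fam, idxs in by_family.items():
        base = fam.replace("miR", "MIR") if fam.startswith("miR") else fam
        for k, idx in enumerate(idxs, start=1):
            name = base if len(idxs) == 1 else f"{base}-{k}"
            candidates[idx].locus_name = f"{prefix}-{name}" if prefix else name
    return candidates


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def candidates_table(candidates: list[PrecursorCandidate]) -> pd.DataFrame:
    """Per-precursor report with the standard metric columns; 'ND' marks an
    arm with no sequenced read.  Contigs with candidates on both strands get
    's'/'a' (sense/antisense) provenance suffixes."""
    strands_per_contig: dict[str, set[str]] = {}
    for c in candidates:
        strands_per_contig.setdefault(c.contig_id, set()).add(c.strand)
    both = {cid for cid, ss in strands_per_contig.items() if len(ss) == 2}
    rows = []
    for c in candidates:
        rep = c.stats.report()
        contig = c.contig_id
        if c.contig_id in both:
            contig += "s" if c.strand == "+" else "a"
        m5, m3 = c.mature_5p, c.mature_3p
        rows.append((
            c.locus_name, contig, rep["length"], f"{rep['gc_percent']:.2f}",
            f"{rep['mfe']:.2f}", f"{rep['amfe']:.2f}", f"{rep['mfei']:.2f}",
            m5[0] if m5 else "ND", m5[1] if m5 else "-",
            m3[0] if m3 else "ND", m3[1] if m3 else "-",
            c.total_reads, c.classification,
            "yes" if c.star_validated else "no"))
    return pd.DataFrame(rows, columns=[
        "name", "contig", "length", "gc_percent", "mfe", "amfe", "mfei",
        "seq_5p", "count_5p", "seq_3p", "count_3p", "total_reads",
        "classification", "star_validated"])


def candidates_gff3(candidates: list[PrecursorCandidate]) -> str:
    """GFF3 (1-based inclusive) of precursor loci."""
    lines = ["##gff-version 3"]
    for c in candidates:
        s, e = c.window
        lines.append("\t".join([
            c.contig_id, "mirseed", "miRNA_primary_transcript",
            str(s + 1), str(e), ".", c.strand, ".",
            f"ID={c.locus_name};class={c.classification}"]))
    return "\n".join(lines) + "\n"


def candidates_dotbracket(candidates: list[PrecursorCandidate]) -> str:
    out = []
    for c in candidates:
        out.append(f">{c.locus_name} {c.contig_id}:{c.window[0] + 1}-"
                   f"{c.window[1]}({c.strand})")
        out.append(str(c.fold))
    return "\n".join(out) + "\n"
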