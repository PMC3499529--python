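"""Synthetic small-RNA study generator with a ground-truth ledger.

Builds transcriptome-like contigs carrying planted hairpin precursors, decoy
contigs, miniature noncoding/organellar reference sets and a miRBase-like
mature reference, then simulates a raw small-RNA FASTQ library over them.

The generator emulates the statistical structure the downstream analysis
assumes: collapsed 18-25 nt reads dominated by 21-nt species, an abundant
mature read block on one hairpin arm and a much rarer star block on the
opposite arm offset by the canonical Dicer 2-nt 3' overhang, plus scattered
background reads drawn from decoy contigs and the reference sets.  Every
emitted read's origin is recorded so each pipeline stage can be checked
against ground truth.

Reads are emitted in the DNA alphabet (sequencers emit DNA); precursors are
folded later in the RNA alphabet.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import pandas as pd

from .sequtils import revcomp_dna, to_dna

NC_CATEGORIES = ("rRNA", "tRNA", "snRNA", "snoRNA", "mtRNA", "cpRNA")

#: Illumina TruSeq small-RNA 3' adapter, the default ligation adapter.
DEFAULT_ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Specs and truth ledger types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrecursorSpec:
    """Recipe for one planted hairpin precursor."""

    mature_seq: str
    arm: str  # "5p" or "3p"
    loop_len: int
    star_mismatches: int = 0
    flank_len: int = 0
    mature_count: int = 1
    star_count: int = 0
    family_label: str | None = None  # None = novel

    def __post_init__(self) -> None:
        object.__setattr__(self, "mature_seq", to_dna(self.mature_seq))
        if not 18 <= len(self.mature_seq) <= 25:
            raise ValueError("mature_seq length must be in [18, 25]")
        if self.arm not in ("5p", "3p"):
            raise ValueError("arm must be '5p' or '3p'")
        if self.loop_len < 4:
            raise ValueError("loop_len must be >= 4 to form a legal hairpin loop")
        if self.star_mismatches < 0 or self.flank_len < 0:
            raise ValueError("star_mismatches and flank_len must be >= 0")
        if self.mature_count < 1:
            raise ValueError("mature_count must be >= 1")
        if not 0 <= self.star_count <= self.mature_count:
            raise ValueError("star_count must be in [0, mature_count]")


@dataclass(frozen=True)
class PlantedLocus:
    """A planted precursor placed on a contig (0-based half-open, forward)."""

    contig_id: str
    start: int
    end: int
    strand: str
    spec: PrecursorSpec
    mature_start: int  # forward-strand contig coords of the mature arm
    mature_end: int
    star_start: int
    star_end: int
    star_seq: str  # star arm as sequenced (same strand as the mature)


@dataclass
class SyntheticTruth:
    """Ground truth for one scenario: contigs, planted loci, references."""

    planted: list[PlantedLocus]
    decoy_contigs: list[str]
    contigs: dict[str, str]
    references: dict[str, list[tuple[str, str]]]
    mature_reference: list[tuple[str, str, str]]  # (name, family, seq)
    seed: int

    @property
    def reference_members(self) -> dict[str, list[str]]:
        return {cat: [sid for sid, _ in seqs] for cat, seqs in self.references.items()}

    def validate(self) -> None:
        for p in self.planted:
            contig = self.contigs[p.contig_id]
            if not (0 <= p.start < p.end <= len(contig)):
                raise ValueError(f"planted interval outside contig: {p}")


# ---------------------------------------------------------------------------
# Precursor construction
# ---------------------------------------------------------------------------


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _mutate(rng: random.Random, seq: str, k: int) -> str:
    """Substitute exactly k positions, each to a different base."""
    if k > len(seq):
        raise ValueError("more mismatches than bases")
    pos = rng.sample(range(len(seq)), k)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in _BASES if b != out[p]])
    return "".join(out)


def build_precursor(spec: PrecursorSpec, rng_seed: int) -> tuple[str, int, int]:
    """Assemble a hairpin precursor: [flank][arm A][loop][arm B][flank].

    The star arm is the reverse complement of the mature arm with exactly
    ``spec.star_mismatches`` substitutions.  Two-nt spacers on either side of
    the loop give the mature/star duplex the canonical Dicer 2-nt 3' overhang
    on each strand, so the total length is
    ``2*len(mature) + loop_len + 4 + 2*flank_len``.

    Returns ``(precursor_seq, mature_offset, star_offset)`` with offsets
    0-based within the precursor.
    """
    rng = random.Random(rng_seed)
    mature = spec.mature_seq
    L = len(mature)
    star = _mutate(rng, revcomp_dna(mature), spec.star_mismatches)
    flank5 = _random_seq(rng, spec.flank_len)
    flank3 = _random_seq(rng, spec.flank_len)
    sp1 = _random_seq(rng, 2)
    loop = _random_seq(rng, spec.loop_len)
    sp2 = _random_seq(rng, 2)
    if spec.arm == "5p":
        seq = flank5 + mature + sp1 + loop + star + sp2 + flank3
        mature_off = len(flank5)
        star_off = len(flank5) + L + 2 + spec.loop_len
    else:
        seq = flank5 + star + sp1 + loop + mature + sp2 + flank3
        star_off = len(flank5)
        mature_off = len(flank5) + L + 2 + spec.loop_len
    return seq, mature_off, star_off


def dinucleotide_shuffle(seq: str, rng: random.Random) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Repeated swaps of interior positions whose flanking bases match: each such
    swap permutes the sequence while leaving the multiset of overlapping
    dimers unchanged.
    """
    n = len(seq)
    if n < 4:
        return seq
    out = list(seq)
    for _ in range(8 * n):
        i, j = rng.sample(range(1, n - 1), 2)
        if abs(i - j) < 2:
            continue
        if out[i - 1] == out[j - 1] and out[i + 1] == out[j + 1]:
            out[i], out[j] = out[j], out[i]
    return "".join(out)


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------

_FAMILY_NUMBERS = (156, 159, 160, 162, 166, 167, 169, 172, 395, 396, 397, 482, 530, 535, 827)
_SPECIES = ("ath", "osa", "ptc", "vvi", "gma")


def make_mature_reference(rng: random.Random, n_families: int = 15,
                          max_members: int = 3) -> list[tuple[str, str, str]]:
    """miRBase-like mature reference: (name, family, seq) with unique seqs."""
    entries: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    fams = _FAMILY_NUMBERS[:n_families]
    for num in fams:
        for m in range(rng.randint(1, max_members)):
            seq = _random_seq(rng, rng.choice((20, 21, 21, 22)))
            if seq in seen:
                continue
            seen.add(seq)
            name = f"{rng.choice(_SPECIES)}-miR{num}{'abcdef'[m]}"
            entries.append((name, f"miR{num}", seq))
    return entries


def make_scenario(seed: int, n_conserved: int = 10, n_novel: int = 10,
                  n_decoys: int = 200, decoy_len: tuple[int, int] = (150, 600),
                  shuffle_decoys_from_planted: bool = False) -> SyntheticTruth:
    """Default study conditions: 20 planted precursors (half conserved, half
    novel), 200 decoy contigs, abundant mature and rare star reads.

    With ``n_conserved = n_novel = 0`` the scenario degenerates to decoys
    only, the negative control for precursor discovery.
    """
    rng = random.Random(seed)
    mature_ref = make_mature_reference(rng)
    contigs: dict[str, str] = {}
    planted: list[PlantedLocus] = []

    # conserved matures drawn from the reference, novel matures random 21-mers
    ref_pool = list(mature_ref)
    rng.shuffle(ref_pool)
    chosen = ref_pool[:n_conserved]
    specs: list[PrecursorSpec] = []
    for name, fam, seq in chosen:
        specs.append(_random_spec(rng, seq, family=fam))
    for _ in range(n_novel):
        ln = 21 if rng.random() < 0.7 else rng.choice((20, 22, 24))
        specs.append(_random_spec(rng, _random_seq(rng, ln), family=None))

    for i, spec in enumerate(specs):
        pre, moff, soff = build_precursor(spec, rng_seed=rng.randrange(2**31))
        pad5 = _random_seq(rng, rng.randint(30, 80))
        pad3 = _random_seq(rng, rng.randint(30, 80))
        strand = rng.choice("+-")
        cid = f"Contig{i + 1:05d}"
        if strand == "+":
            contig = pad5 + pre + pad3
            start = len(pad5)
            m_s = start + moff
            s_s = start + soff
            m_e, s_e = m_s + len(spec.mature_seq), s_s + len(spec.mature_seq)
        else:
            contig = pad5 + revcomp_dna(pre) + pad3
            start = len(pad5)
            end_ = start + len(pre)
            m_e = end_ - moff
            m_s = m_e - len(spec.mature_seq)
            s_e = end_ - soff
            s_s = s_e - len(spec.mature_seq)
        star_seq = pre[soff:soff + len(spec.mature_seq)]
        contigs[cid] = contig
        planted.append(PlantedLocus(
            contig_id=cid, start=start, end=start + len(pre), strand=strand,
            spec=spec, mature_start=m_s, mature_end=m_e,
            star_start=s_s, star_end=s_e, star_seq=star_seq))

    decoy_ids: list[str] = []
    planted_seqs = [contigs[p.contig_id] for p in planted]
    for d in range(n_decoys):
        cid = f"Decoy{d + 1:05d}"
        if shuffle_decoys_from_planted and planted_seqs:
            src = rng.choice(planted_seqs)
            seq = dinucleotide_shuffle(src, rng)
        else:
            gc = rng.uniform(0.35, 0.55)
            seq = "".join(
                rng.choice("GC") if rng.random() < gc else rng.choice("AT")
                for _ in range(rng.randint(*decoy_len)))
        contigs[cid] = seq
        decoy_ids.append(cid)

    references = {
        cat: [(f"{cat}_{k + 1}", _random_seq(rng, rng.randint(100, 400)))
              for k in range(rng.randint(2, 4))]
        for cat in NC_CATEGORIES
    }
    truth = SyntheticTruth(planted=planted, decoy_contigs=decoy_ids,
                           contigs=contigs, references=references,
                           mature_reference=mature_ref, seed=seed)
    truth.validate()
    return truth


def _random_spec(rng: random.Random, mature: str, family: str | None) -> PrecursorSpec:
    mature_count = int(round(50 * (5000 / 50) ** rng.random()))  # log-uniform 50..5000
    star_count = max(1, int(mature_count * rng.uniform(0.005, 0.05)))
    return PrecursorSpec(
        mature_seq=mature,
        arm=rng.choice(("5p", "3p")),
        loop_len=rng.randint(8, 40),
        star_mismatches=0 if rng.random() < 0.8 else 1,
        flank_len=rng.randint(10, 30),
        mature_count=mature_count,
        star_count=star_count,
        family_label=family,
    )


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------

#: background-read origin mixture over decoys and reference categories
BACKGROUND_MIX = (
    ("decoy", 0.50), ("rRNA", 0.20), ("cpRNA", 0.10), ("mtRNA", 0.08),
    ("tRNA", 0.07), ("snRNA", 0.03), ("snoRNA", 0.02),
)

_HIGH_Q = "I"  # Q40
_LOW_Q = "#"   # Q2


def simulate_library(truth: SyntheticTruth, background_reads: int,
                     adapter3p: str = DEFAULT_ADAPTER_3P, rng_seed: int = 0,
                     read_len: int = 50, low_quality_fraction: float = 0.0,
                     ) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Emit raw FASTQ records (id, seq, qual) and the origin ledger.

    Mature/star reads are emitted at their specified counts; background reads
    are drawn from decoy contigs and reference sets with lengths uniform on
    [18, 25].  Every read is insert + 3' adapter, padded with A (or truncated)
    to ``read_len``.  Exactly ``round(low_quality_fraction * total)`` reads
    get a sub-threshold quality string; the ledger flags which.
    """
    if background_reads < 0:
        raise ValueError("background_reads must be >= 0")
    if not adapter3p:
        raise ValueError("adapter3p must be non-empty")
    rng = random.Random(rng_seed)
    inserts: list[tuple[str, str, str, int, int, str]] = []  # insert, origin, contig, s, e, strand

    for p in truth.planted:
        for _ in range(p.spec.mature_count):
            inserts.append((p.spec.mature_seq, "mature", p.contig_id,
                            p.mature_start, p.mature_end, p.strand))
        for _ in range(p.spec.star_count):
            inserts.append((p.star_seq, "star", p.contig_id,
                            p.star_start, p.star_end, p.strand))

    weights = [w for _, w in BACKGROUND_MIX]
    origins = [o for o, _ in BACKGROUND_MIX]
    for _ in range(background_reads):
        origin = rng.choices(origins, weights)[0]
        ln = rng.randint(18, 25)
        if origin != "decoy" and not truth.references.get(origin):
            origin = "decoy"  # scenario has no such reference set
        if origin == "decoy":
            if not truth.decoy_contigs:
                continue  # nothing to draw background from
            cid = rng.choice(truth.decoy_contigs)
            src = truth.contigs[cid]
        else:
            cid, src = rng.choice(truth.references[origin])
        if len(src) < ln:
            continue
        s = rng.randrange(len(src) - ln + 1)
        sub = src[s:s + ln]
        strand = rng.choice("+-")
        insert = sub if strand == "+" else revcomp_dna(sub)
        inserts.append((insert, origin, cid, s, s + ln, strand))

    n = len(inserts)
    k_low = int(round(low_quality_fraction * n))
    low_idx = set(rng.sample(range(n), k_low)) if k_low else set()

    records: list[tuple[str, str, str]] = []
    rows = []
    for i, (insert, origin, cid, s, e, strand) in enumerate(inserts):
        rid = f"read{i + 1:07d}"
        seq = (insert + adapter3p)[:read_len]
        seq = seq + "A" * (read_len - len(seq))
        qual = (_LOW_Q if i in low_idx else _HIGH_Q) * read_len
        records.append((rid, seq, qual))
        rows.append((rid, origin, cid, s, e, strand, i in low_idx, insert))
    ledger = pd.DataFrame(rows, columns=[
        "read_id", "origin", "contig", "start", "end", "strand",
        "low_quality", "insert"])
    return records, ledger


# ---------------------------------------------------------------------------
# Plain-text writers
# ---------------------------------------------------------------------------


def write_fastq(records: list[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_fasta(entries, path) -> None:
    """Write (id, seq) pairs or a dict as FASTA."""
    items = entries.items() if hasattr(entries, "items") else entries
    with open(path, "w") as fh:
        for sid, seq in items:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_ledger(ledger: pd.DataFrame, path) -> None:
    ledger.to_csv(path, sep="\t", index=False)
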