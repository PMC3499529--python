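"""Shared sequence primitives: alphabet normalization, complements, rounding.

Sequencers emit DNA (T); RNA folding runs on RNA (U).  All T<->U mapping in the
package goes through :func:`to_dna` / :func:`to_rna` so the two alphabets can
never mix silently.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def to_dna(seq: str) -> str:
    """Uppercase and map U->T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and map T->U."""
    return seq.upper().replace("T", "U")


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.upper().translate(_RNA_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction of a non-empty sequence (alphabet-agnostic)."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def round_half_up(x: float | Decimal, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as in printed reports.

    Uses decimal arithmetic so values like -42.875 round to -42.88 rather
    than drifting through binary representation to -42.87.
    """
    d = x if isinstance(x, Decimal) else Decimal(repr(x))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))
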