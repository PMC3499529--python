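"""Minimum-free-energy hairpin folding and precursor energy statistics.

The folding engine predicts a nested (pseudoknot-free) secondary structure
under a deliberately small, fully documented nearest-neighbor model:

* stacking energies for adjacent Watson-Crick pairs from a built-in 16-entry
  table (``STACK_WC``); any stack involving a G·U wobble gets the constant
  ``GU_STACK``;
* hairpin and bulge/internal loops charged as affine functions of loop size;
* multibranch loops charged a flat closing penalty;
* minimum hairpin loop of 3 unpaired bases; lonely pairs allowed; interior
  loops larger than ``MAX_INTERIOR`` nt are disallowed.

The model is self-consistent rather than thermodynamically calibrated: the
same energy function is shared by the O(n^3) dynamic program, the independent
exhaustive enumerator used to certify DP optimality on short sequences, and
the re-scoring of returned structures.  Published MFE values are therefore
treated as *inputs* when computing AMFE/MFEI report statistics
(:func:`stats_from_metrics`), and the engine is validated by construction
properties (planted hairpins fold into their planted stems) rather than by
matching any external parameter set.

Energy statistics follow the standard plant pre-miRNA descriptors:
AMFE = 100 * MFE / length (kcal/mol per 100 nt) and
MFEI = AMFE / GC% (GC expressed as a percentage, e.g. 54.64).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Iterator

import numpy as np
from numba import njit

from .sequtils import RNA_ALPHABET, round_half_up, to_rna

# ---------------------------------------------------------------------------
# Energy model constants (kcal/mol)
# ---------------------------------------------------------------------------

#: 16-entry Watson-Crick stacking table.  Key (p, q): pair p = (5'i, 3'j)
#: closing the stack, pair q = (i+1, j-1) stacked on it.
STACK_WC: dict[tuple[str, str], float] = {
    ("AU", "AU"): -0.9, ("AU", "UA"): -1.1, ("AU", "CG"): -2.2, ("AU", "GC"): -2.1,
    ("UA", "AU"): -1.3, ("UA", "UA"): -0.9, ("UA", "CG"): -2.4, ("UA", "GC"): -2.1,
    ("CG", "AU"): -2.1, ("CG", "UA"): -2.1, ("CG", "CG"): -3.3, ("CG", "GC"): -2.4,
    ("GC", "AU"): -2.4, ("GC", "UA"): -2.2, ("GC", "CG"): -3.4, ("GC", "GC"): -3.3,
}

#: Stacking energy when either pair of the stack is a G·U wobble.
GU_STACK: float = -0.5

HAIRPIN_A: float = 4.0   #: hairpin closing penalty, constant term
HAIRPIN_B: float = 0.25  #: hairpin penalty per unpaired loop base
INTERIOR_A: float = 2.0  #: bulge/internal loop, constant term
INTERIOR_B: float = 0.4  #: bulge/internal loop, per unpaired base
MULTI_C: float = 3.4     #: multibranch loop closing penalty (flat)
MIN_HAIRPIN: int = 3     #: minimum unpaired bases in a hairpin loop
MAX_INTERIOR: int = 30   #: largest bulge/internal loop size considered

_INF = 1e9
_EPS = 1e-7

# base encoding A=0 C=1 G=2 U=3
_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}
_PAIR_NAMES = {(0, 3): "AU", (3, 0): "UA", (1, 2): "CG", (2, 1): "GC"}
_WOBBLE = {(2, 3), (3, 2)}

# dense tables for the numba kernel: -1 = not pairable, 0..3 = WC index, 4 = GU
_PAIR_CODE = np.full((4, 4), -1, dtype=np.int8)
for _i, (_bp, _nm) in enumerate((((0, 3), "AU"), ((3, 0), "UA"), ((1, 2), "CG"), ((2, 1), "GC"))):
    _PAIR_CODE[_bp] = _i
for _bp in _WOBBLE:
    _PAIR_CODE[_bp] = 4

_STACK_TABLE = np.full((5, 5), GU_STACK, dtype=np.float64)
_WC_ORDER = ["AU", "UA", "CG", "GC"]
for _a in range(4):
    for _b in range(4):
        _STACK_TABLE[_a, _b] = STACK_WC[(_WC_ORDER[_a], _WC_ORDER[_b])]


def can_pair(a: str, b: str) -> bool:
    """Watson-Crick or G·U wobble pairing between two RNA bases."""
    x, y = _ENC.get(a, -1), _ENC.get(b, -1)
    if x < 0 or y < 0:
        return False
    return _PAIR_CODE[x, y] >= 0


def stack_energy(outer: tuple[str, str], inner: tuple[str, str]) -> float:
    """Energy of pair ``inner`` stacked directly on pair ``outer``."""
    ko, ki = "".join(outer), "".join(inner)
    if ko in _WC_ORDER and ki in _WC_ORDER:
        return STACK_WC[(ko, ki)]
    return GU_STACK


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldResult:
    """An MFE structure: sequence, dot-bracket, energy, symmetric pair table."""

    seq: str
    structure: str
    mfe: float
    pair_table: dict[int, int]

    def paired_partner(self, i: int) -> int | None:
        return self.pair_table.get(i)

    def __str__(self) -> str:  # Vienna-style dot-bracket block
        return f"{self.seq}\n{self.structure} ({self.mfe:.2f})"


@dataclass(frozen=True)
class PrecursorStats:
    """Length/GC/MFE descriptors of a precursor; exact decimal internals.

    ``amfe`` and ``mfei`` are unrounded; use :meth:`report` for the 2-decimal
    half-up values that appear in tables.
    """

    length: int
    gc_percent: float
    mfe: float
    amfe: float
    mfei: float
    _amfe_exact: Decimal
    _mfei_exact: Decimal

    def report(self) -> dict[str, float]:
        return {
            "length": self.length,
            "gc_percent": round_half_up(Decimal(repr(self.gc_percent))),
            "mfe": round_half_up(Decimal(repr(self.mfe))),
            "amfe": round_half_up(self._amfe_exact),
            "mfei": round_half_up(self._mfei_exact),
        }


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def gc_percent(seq: str) -> float:
    """G+C content as a percentage of sequence length."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return float(Decimal((s.count("G") + s.count("C")) * 100) / Decimal(len(s)))


def stats_from_metrics(length: int, gc: float | str | Decimal,
                       mfe: float | str | Decimal) -> PrecursorStats:
    """AMFE/MFEI identities from already-known length, GC% and MFE.

    Arithmetic is done in decimal so printed inputs like -68.60/160 hit the
    exact tie -42.875 and round half-up to -42.88.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    gc_d = gc if isinstance(gc, Decimal) else Decimal(str(gc))
    mfe_d = mfe if isinstance(mfe, Decimal) else Decimal(str(mfe))
    amfe = mfe_d * 100 / Decimal(length)
    mfei = amfe / gc_d if gc_d != 0 else Decimal(0)
    return PrecursorStats(
        length=length,
        gc_percent=float(gc_d),
        mfe=float(mfe_d),
        amfe=float(amfe),
        mfei=float(mfei),
        _amfe_exact=amfe,
        _mfei_exact=mfei,
    )


def precursor_stats(seq: str, mfe: float) -> PrecursorStats:
    """Descriptors for a folded precursor sequence with MFE ``mfe``."""
    if mfe > _EPS:
        raise ValueError("mfe must be <= 0")
    s = seq.upper()
    gc_d = Decimal((s.count("G") + s.count("C")) * 100) / Decimal(len(s))
    return stats_from_metrics(len(s), gc_d, Decimal(repr(float(mfe))))


# ---------------------------------------------------------------------------
# Dynamic programming fold
# ---------------------------------------------------------------------------


@njit(cache=False)
def _fill(code, pair_code, stack_table, ha, hb, ia, ib, mc, max_int):  # pragma: no cover
    n = code.shape[0]
    INF = 1e9
    V = np.full((n, n), INF)
    M = np.full((n, n), INF)   # >=1 branch in region
    M2 = np.full((n, n), INF)  # >=2 branches in region
    for j in range(n):
        for i in range(j, -1, -1):
            if j - i - 1 >= 3 and pair_code[code[i], code[j]] >= 0:
                best = ha + hb * (j - i - 1)
                # stacked pair / bulge / internal loop
                kmax = min(i + max_int + 1, j - 4)
                for k in range(i + 1, kmax + 1):
                    left = k - i - 1
                    lmin = max(k + 4, j - 1 - (max_int - left))
                    for l in range(j - 1, lmin - 1, -1):
                        if V[k, l] >= INF:
                            continue
                        size = left + (j - l - 1)
                        if size == 0:
                            pi = pair_code[code[i], code[j]]
                            pk = pair_code[code[k], code[l]]
                            e = stack_table[pi, pk] + V[k, l]
                        else:
                            e = ia + ib * size + V[k, l]
                        if e < best:
                            best = e
                # multibranch
                if j - i - 1 >= 2 and M2[i + 1, j - 1] < INF:
                    e = mc + M2[i + 1, j - 1]
                    if e < best:
                        best = e
                V[i, j] = best
            # M / M2 over region [i, j]
            m = M[i, j - 1] if j > i else INF
            if V[i, j] < m:
                m = V[i, j]
            m2 = M2[i, j - 1] if j > i else INF
            for k in range(i + 1, j - 3):
                if V[k, j] < INF and M[i, k - 1] < INF:
                    e = M[i, k - 1] + V[k, j]
                    if e < m:
                        m = e
                    if e < m2:
                        m2 = e
            M[i, j] = m
            M2[i, j] = m2
    # exterior: suffix minimum
    W = np.zeros(n + 1)
    for i in range(n - 1, -1, -1):
        w = W[i + 1]
        for j in range(i + 4, n):
            if V[i, j] < INF:
                e = V[i, j] + W[j + 1]
                if e < w:
                    w = e
        W[i] = w
    return V, M, M2, W


def _traceback(n: int, V, M, M2, W) -> dict[int, int]:
    """Recover one optimal structure; deterministic, preferring the 5'-most
    pairing whenever alternatives tie."""
    pairs: dict[int, int] = {}
    tasks: list[tuple] = [("W", 0)]
    while tasks:
        t = tasks.pop()
        kind = t[0]
        if kind == "W":
            i = t[1]
            if i >= n:
                continue
            placed = False
            for j in range(i + 4, n):
                if V[i, j] + W[j + 1] <= W[i] + _EPS:
                    pairs[i] = j
                    pairs[j] = i
                    tasks.append(("W", j + 1))
                    tasks.append(("V", i, j))
                    placed = True
                    break
            if not placed:
                tasks.append(("W", i + 1))
        elif kind == "V":
            i, j = t[1], t[2]
            e = V[i, j]
            if abs(e - (HAIRPIN_A + HAIRPIN_B * (j - i - 1))) <= _EPS:
                continue
            found = False
            kmax = min(i + MAX_INTERIOR + 1, j - 4)
            for k in range(i + 1, kmax + 1):
                left = k - i - 1
                lmin = max(k + 4, j - 1 - (MAX_INTERIOR - left))
                for l in range(j - 1, lmin - 1, -1):
                    if V[k, l] >= _INF:
                        continue
                    size = left + (j - l - 1)
                    cost = _interior_cost(size, i, j, k, l)
                    if abs(cost + V[k, l] - e) <= _EPS:
                        pairs[k] = l
                        pairs[l] = k
                        tasks.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if not found:
                tasks.append(("M2", i + 1, j - 1))
        elif kind == "M2":
            i, j = t[1], t[2]
            if j > i and abs(M2[i, j] - M2[i, j - 1]) <= _EPS:
                tasks.append(("M2", i, j - 1))
                continue
            for k in range(i + 1, j - 3):
                if abs(M[i, k - 1] + V[k, j] - M2[i, j]) <= _EPS:
                    pairs[k] = j
                    pairs[j] = k
                    tasks.append(("V", k, j))
                    tasks.append(("M", i, k - 1))
                    break
        elif kind == "M":
            i, j = t[1], t[2]
            if j > i and abs(M[i, j] - M[i, j - 1]) <= _EPS:
                tasks.append(("M", i, j - 1))
                continue
            if abs(V[i, j] - M[i, j]) <= _EPS:
                pairs[i] = j
                pairs[j] = i
                tasks.append(("V", i, j))
                continue
            for k in range(i + 1, j - 3):
                if abs(M[i, k - 1] + V[k, j] - M[i, j]) <= _EPS:
                    pairs[k] = j
                    pairs[j] = k
                    tasks.append(("V", k, j))
                    tasks.append(("M", i, k - 1))
                    break
    return pairs


_current_code: np.ndarray | None = None


def _interior_cost(size: int, i: int, j: int, k: int, l: int) -> float:
    if size == 0:
        assert _current_code is not None
        pi = _PAIR_CODE[_current_code[i], _current_code[j]]
        pk = _PAIR_CODE[_current_code[k], _current_code[l]]
        return float(_STACK_TABLE[pi, pk])
    return INTERIOR_A + INTERIOR_B * size


def fold_mfe(seq: str) -> FoldResult:
    """Minimum-free-energy structure of an RNA (or DNA-alphabet) sequence.

    Accepts 10..2000 nt; raises on other lengths or non-ACGU(T) characters.
    """
    global _current_code
    rna = to_rna(seq)
    if not (10 <= len(rna) <= 2000):
        raise ValueError(f"sequence length {len(rna)} outside [10, 2000]")
    if not set(rna) <= RNA_ALPHABET:
        bad = sorted(set(rna) - RNA_ALPHABET)
        raise ValueError(f"invalid characters in sequence: {bad}")
    code = np.array([_ENC[c] for c in rna], dtype=np.int8)
    V, M, M2, W = _fill(code, _PAIR_CODE, _STACK_TABLE,
                        HAIRPIN_A, HAIRPIN_B, INTERIOR_A, INTERIOR_B,
                        MULTI_C, MAX_INTERIOR)
    _current_code = code
    try:
        pairs = _traceback(len(rna), V, M, M2, W)
    finally:
        _current_code = None
    structure = _dot_bracket(len(rna), pairs)
    return FoldResult(seq=rna, structure=structure, mfe=float(W[0]), pair_table=pairs)


def _dot_bracket(n: int, pairs: dict[int, int]) -> str:
    out = ["."] * n
    for i, j in pairs.items():
        if i < j:
            out[i] = "("
            out[j] = ")"
    return "".join(out)


# ---------------------------------------------------------------------------
# Independent scoring and exhaustive enumeration (oracle path)
# ---------------------------------------------------------------------------


def structure_energy(seq: str, pairs: dict[int, int]) -> float:
    """Score an arbitrary nested structure under the package energy model.

    Independent of the DP: walks the loop decomposition of the pair tree.
    Returns +inf for structures the model disallows (bad pairs, hairpin
    loops < 3, interior loops > ``MAX_INTERIOR``).
    """
    rna = to_rna(seq)
    plist = sorted((i, j) for i, j in pairs.items() if i < j)
    for i, j in plist:
        if not can_pair(rna[i], rna[j]):
            return _INF
    # build tree of directly-enclosed pairs
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in plist}
    root: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = []
    for p in plist:
        while stack and p[0] > stack[-1][1]:
            stack.pop()
        if stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            return _INF  # crossing pairs
        (children[stack[-1]] if stack else root).append(p)
        stack.append(p)
    total = 0.0
    for (i, j), kids in children.items():
        if not kids:
            loop = j - i - 1
            if loop < MIN_HAIRPIN:
                return _INF
            total += HAIRPIN_A + HAIRPIN_B * loop
        elif len(kids) == 1:
            (k, l) = kids[0]
            size = (k - i - 1) + (j - l - 1)
            if size == 0:
                total += stack_energy((rna[i], rna[j]), (rna[k], rna[l]))
            elif size > MAX_INTERIOR:
                return _INF
            else:
                total += INTERIOR_A + INTERIOR_B * size
        else:
            total += MULTI_C
    return total


def enumerate_structures(seq: str) -> Iterator[dict[int, int]]:
    """Yield every legal nested structure (incl. empty) of a short sequence.

    Intended for sequences up to ~18 nt where exhaustive enumeration is the
    optimality oracle for the DP.
    """
    rna = to_rna(seq)
    n = len(rna)

    def region(i: int, j: int) -> list[list[tuple[int, int]]]:
        if j - i + 1 < MIN_HAIRPIN + 2:
            return [[]]
        out = list(region(i + 1, j))
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if can_pair(rna[i], rna[k]):
                inner = region(i + 1, k - 1)
                outer = region(k + 1, j)
                for a in inner:
                    for b in outer:
                        out.append([(i, k), *a, *b])
        return out

    for plist in region(0, n - 1):
        yield {**{i: j for i, j in plist}, **{j: i for i, j in plist}}


def fold_exhaustive(seq: str) -> float:
    """Brute-force MFE by scoring every enumerable structure; oracle for
    :func:`fold_mfe` on short inputs."""
    best = 0.0
    rna = to_rna(seq)
    for pairs in enumerate_structures(rna):
        e = structure_energy(rna, pairs)
        if e < best:
            best = e
    return best
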