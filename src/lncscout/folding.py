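"""Minimum-free-energy RNA secondary structure by dynamic programming.

A base-pair energy model (GC/CG -3, AU/UA -2, GU/UG -1 kcal/mol, minimum
hairpin loop of 3 unpaired bases) folded exactly by a Nussinov-style
O(n^3) recursion.  This deliberately simple model preserves the
GC-dependence of folding stability that drives class contrasts while
remaining checkable against exhaustive enumeration; its absolute energies
are not comparable to nearest-neighbor (Turner-parameter) values.

T is read as U.  A flag forbids lonely pairs by requiring every helix to
be at least two pairs deep from its outermost pair (slightly conservative
relative to the usual --noLP convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .families import encode

MIN_HAIRPIN = 3

# pair energies indexed by (code_a, code_b); 0 = not pairable
_PAIR_E = np.zeros((4, 4))
_PAIR_E[2, 1] = _PAIR_E[1, 2] = -3.0  # G-C
_PAIR_E[0, 3] = _PAIR_E[3, 0] = -2.0  # A-U
_PAIR_E[2, 3] = _PAIR_E[3, 2] = -1.0  # G-U


@dataclass
class FoldResult:
    contig_id: str
    mfe: float  # kcal/mol, <= 0
    structure: str  # dot-bracket
    length_corrected_mfe: float  # kcal/mol per nt

    def pair_list(self) -> list[tuple[int, int]]:
        stack, pairs = [], []
        for i, ch in enumerate(self.structure):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                pairs.append((stack.pop(), i))
        return pairs


@njit(cache=True)
def _fill(codes, pair_e, min_hairpin, no_lonely):  # pragma: no cover - numba
    n = codes.shape[0]
    M = np.zeros((n, n))  # M[i, j] = min energy over codes[i..j] inclusive
    for span in range(min_hairpin + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i, j - 1]  # j unpaired
            for k in range(i, j - min_hairpin):
                e = pair_e[codes[k], codes[j]]
                if e >= 0.0:
                    continue
                if no_lonely:
                    if k + 1 >= j - 1:
                        continue
                    e_in = pair_e[codes[k + 1], codes[j - 1]]
                    if e_in >= 0.0:
                        continue
                    if (j - 1) - (k + 1) <= min_hairpin:
                        continue
                    inner = M[k + 2, j - 2] if k + 2 <= j - 2 else 0.0
                    cand = e + e_in + inner
                else:
                    inner = M[k + 1, j - 1] if k + 1 <= j - 1 else 0.0
                    cand = e + inner
                if k > i:
                    cand += M[i, k - 1]
                if cand < best:
                    best = cand
            M[i, j] = best
    return M


@njit(cache=True)
def _traceback(codes, M, pair_e, min_hairpin, no_lonely):  # pragma: no cover
    n = codes.shape[0]
    partner = np.full(n, -1, dtype=np.int64)
    stack_i = np.empty(2 * n + 4, dtype=np.int64)
    stack_j = np.empty(2 * n + 4, dtype=np.int64)
    top = 0
    stack_i[top] = 0
    stack_j[top] = n - 1
    top += 1
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        if j - i <= min_hairpin:
            continue
        target = M[i, j]
        if target == 0.0:
            continue
        found = False
        # prefer a pairing decision (outermost-first), then j unpaired
        for k in range(i, j - min_hairpin):
            e = pair_e[codes[k], codes[j]]
            if e >= 0.0:
                continue
            if no_lonely:
                if k + 1 >= j - 1:
                    continue
                e_in = pair_e[codes[k + 1], codes[j - 1]]
                if e_in >= 0.0:
                    continue
                if (j - 1) - (k + 1) <= min_hairpin:
                    continue
                inner = M[k + 2, j - 2] if k + 2 <= j - 2 else 0.0
                cand = e + e_in + inner
            else:
                inner = M[k + 1, j - 1] if k + 1 <= j - 1 else 0.0
                cand = e + inner
            if k > i:
                cand += M[i, k - 1]
            if cand == target:
                partner[k] = j
                partner[j] = k
                if no_lonely:
                    partner[k + 1] = j - 1
                    partner[j - 1] = k + 1
                    if k + 2 <= j - 2:
                        stack_i[top] = k + 2
                        stack_j[top] = j - 2
                        top += 1
                else:
                    if k + 1 <= j - 1:
                        stack_i[top] = k + 1
                        stack_j[top] = j - 1
                        top += 1
                if k > i:
                    stack_i[top] = i
                    stack_j[top] = k - 1
                    top += 1
                found = True
                break
        if not found:
            stack_i[top] = i
            stack_j[top] = j - 1
            top += 1
    return partner


def fold_mfe(
    sequence: str,
    contig_id: str = "",
    no_lonely_pairs: bool = False,
    min_hairpin: int = MIN_HAIRPIN,
) -> FoldResult:
    """Energy-minimizing nested structure of an RNA (or DNA-alphabet) string.

    Raises on non-nucleotide symbols.  Ties in the traceback prefer a
    pairing over leaving the 3' base unpaired, scanning pairing partners
    outermost-first, so the reported structure is deterministic.
    """
    codes = encode(sequence)  # validates alphabet; T read as U
    n = len(codes)
    if n == 0:
        raise ValueError("empty sequence")
    if n <= min_hairpin + 1:
        return FoldResult(contig_id, 0.0, "." * n, 0.0)
    M = _fill(codes, _PAIR_E, min_hairpin, no_lonely_pairs)
    mfe = float(M[0, n - 1])
    partner = _traceback(codes, M, _PAIR_E, min_hairpin, no_lonely_pairs)
    structure = "".join(
        "." if p < 0 else ("(" if p > i else ")") for i, p in enumerate(partner)
    )
    return FoldResult(contig_id, mfe, structure, mfe / n)


def structure_energy(sequence: str, structure: str) -> float:
    """Re-sum the pair energies of a dot-bracket structure."""
    codes = encode(sequence)
    stack, total = [], 0.0
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            total += _PAIR_E[codes[j], codes[i]]
    if stack:
        raise ValueError("unbalanced structure")
    return total


def enumerate_structures(sequence: str, min_hairpin: int = MIN_HAIRPIN):
    """Yield (energy, pair set) of every legal nested structure (oracle use).

    Exponential; intended for sequences of length <= ~12.
    """
    codes = encode(sequence)

    def rec(i: int, j: int):
        # all structures on codes[i..j]
        if j - i < 0:
            yield 0.0, frozenset()
            return
        # j unpaired
        for e, ps in rec(i, j - 1):
            yield e, ps
        for k in range(i, j - min_hairpin):
            e_pair = _PAIR_E[codes[k], codes[j]]
            if e_pair >= 0.0:
                continue
            for e1, p1 in rec(i, k - 1):
                for e2, p2 in rec(k + 1, j - 1):
                    yield e_pair + e1 + e2, p1 | p2 | {(k, j)}

    yield from rec(0, len(codes) - 1)
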