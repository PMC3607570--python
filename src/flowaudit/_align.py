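"""Deterministic affine-gap pairwise alignment (Gotoh) used by the
change quantifier and the event-distance calculator.

Terminal-gap handling is controlled per end:

* ``free_head=False, free_tail=False`` — ordinary global alignment.
* ``free_tail=True`` — trailing gap runs are unpenalised and excluded
  from the traced path: the signed 3' overhang between two pipeline
  stages can be measured without contamination from internal indels.
* ``free_head=True`` — leading gap runs are likewise free (overlap
  alignment, used for the event distance, where terminal gaps are
  ignored entirely).  When the head is *not* free, leading gaps are
  penalised like any other gap, which anchors the alignment at the 5'
  end — reads compared across stages share their 5' start, so without
  this anchor a periodic sequence would leave the 3'-overhang placement
  ambiguous.

Conventions, fixed for reproducibility:

* Gap cost: the first gap column of a run costs ``gap_open``, each
  further column ``gap_extend``; both are <= 0 and ``gap_open <=
  gap_extend`` is required (re-opening a gap can then never beat
  extending one, which the row-vectorised recurrence exploits).
* Traceback tie-break priority: diagonal > vertical (query base over a
  reference gap) > horizontal.
* Overhang ties in overlap mode: the smaller overhang wins; a residual
  tie between a query-side and a reference-side overhang of the same
  length is broken toward the lexicographically greater sequence, so
  the signed overhang is antisymmetric under argument swap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_EPS = 1e-9
NEG_INF = -1e30

# IUPAC membership used for degenerate-code-aware scoring
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_CODE_OF = np.zeros(256, dtype=np.int8)
_ALPHABET = "ACGTURYSWKMBDHVN"
for _i, _c in enumerate(_ALPHABET):
    _CODE_OF[ord(_c)] = _i
    _CODE_OF[ord(_c.lower())] = _i

def _compat_matrix() -> np.ndarray:
    n = len(_ALPHABET)
    mat = np.zeros((n, n), dtype=bool)
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            sa, sb = set(_IUPAC[a]), set(_IUPAC[b])
            # tolerated when one code's member set contains the other's
            mat[i, j] = sa <= sb or sb <= sa
    return mat

_COMPAT = _compat_matrix()


def compatible(a: str, b: str) -> bool:
    """True when one symbol's IUPAC member set contains the other's."""
    return bool(_COMPAT[_CODE_OF[ord(a)], _CODE_OF[ord(b)]])


def _encode(seq: str) -> np.ndarray:
    return _CODE_OF[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class Alignment:
    """A traced pairwise alignment.

    ``ops`` is a string over {M, I, D}: M consumes one base of each
    sequence (match or substitution), I consumes a query base only,
    D a reference base only.  Free terminal overhangs are *not* part
    of ``ops``; they are reported as signed ``overhang5`` /
    ``overhang3`` (positive: unaligned query bases, negative:
    unaligned reference bases).
    """

    query: str
    ref: str
    score: float
    ops: str
    q_start: int
    r_start: int
    overhang5: int
    overhang3: int

    def columns(self):
        """Yield (query_char, ref_char) pairs, '-' for gaps."""
        qi, ri = self.q_start, self.r_start
        for op in self.ops:
            if op == "M":
                yield self.query[qi], self.ref[ri]
                qi += 1
                ri += 1
            elif op == "I":
                yield self.query[qi], "-"
                qi += 1
            else:
                yield "-", self.ref[ri]
                ri += 1


def align(
    query: str,
    ref: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
    free_head: bool = False,
    free_tail: bool = False,
    iupac_tolerant: bool = False,
) -> Alignment:
    """Optimal pairwise alignment under the module's fixed conventions."""
    if not query or not ref:
        raise ValueError("cannot align an empty sequence")
    if not (gap_open <= gap_extend <= 0):
        raise ValueError("require gap_open <= gap_extend <= 0")
    q = _encode(query)
    r = _encode(ref)
    L1, L2 = len(q), len(r)

    if iupac_tolerant:
        smat = np.where(_COMPAT, match, mismatch)
    else:
        eye = np.eye(len(_ALPHABET), dtype=bool)
        eye[_ALPHABET.index("U"), _ALPHABET.index("T")] = True
        eye[_ALPHABET.index("T"), _ALPHABET.index("U")] = True
        smat = np.where(eye, match, mismatch)
    sub_rows = smat[q][:, r]  # (L1, L2) substitution scores

    H = np.empty((L1 + 1, L2 + 1))
    E = np.full((L1 + 1, L2 + 1), NEG_INF)  # gap in query (left moves)
    F = np.full((L1 + 1, L2 + 1), NEG_INF)  # gap in ref (up moves)

    cols = np.arange(L2 + 1, dtype=float)
    if free_head:
        H[0, :] = 0.0
        H[:, 0] = 0.0
    else:
        H[0, 0] = 0.0
        H[0, 1:] = gap_open + gap_extend * (cols[1:] - 1)
        H[1:, 0] = gap_open + gap_extend * np.arange(L1, dtype=float)
        E[0, 1:] = H[0, 1:]
        F[1:, 0] = H[1:, 0]

    ext_off = gap_extend * cols
    for i in range(1, L1 + 1):
        F[i, :] = np.maximum(F[i - 1, :] + gap_extend, H[i - 1, :] + gap_open)
        h0 = np.empty(L2 + 1)
        h0[0] = H[i, 0]
        h0[1:] = np.maximum(H[i - 1, :-1] + sub_rows[i - 1], F[i, 1:])
        if not free_head:
            h0[0] = max(h0[0], F[i, 0])
        # E via prefix-max: valid because gap_open <= gap_extend means a
        # gap never profitably re-opens out of another gap in the same row
        cm = np.maximum.accumulate(h0 - ext_off)
        E[i, 1:] = gap_open + ext_off[1:] - gap_extend + cm[:-1]
        H[i, :] = np.maximum(h0, E[i, :])

    # --- choose the end cell -------------------------------------------------
    if free_tail:
        end_i, end_j, overhang3 = _pick_end(H, query, ref)
        score = float(H[end_i, end_j])
    else:
        end_i, end_j, overhang3 = L1, L2, 0
        score = float(H[L1, L2])

    # --- traceback -----------------------------------------------------------
    ops: list[str] = []
    i, j = end_i, end_j
    state = "H"
    while True:
        if free_head and (i == 0 or j == 0):
            break
        if not free_head and i == 0 and j == 0:
            break
        if state == "H":
            if not free_head and i == 0:
                ops.append("D")
                j -= 1
                continue
            if not free_head and j == 0:
                ops.append("I")
                i -= 1
                continue
            h = H[i, j]
            if abs(h - (H[i - 1, j - 1] + sub_rows[i - 1, j - 1])) < _EPS:
                ops.append("M")
                i -= 1
                j -= 1
            elif abs(h - F[i, j]) < _EPS:
                state = "F"
            elif abs(h - E[i, j]) < _EPS:
                state = "E"
            else:  # pragma: no cover - would indicate a filling bug
                raise AssertionError(f"traceback stuck at ({i},{j})")
        elif state == "F":
            ops.append("I")
            if abs(F[i, j] - (H[i - 1, j] + gap_open)) < _EPS:
                state = "H"
            i -= 1
        else:  # state == "E"
            ops.append("D")
            if abs(E[i, j] - (H[i, j - 1] + gap_open)) < _EPS:
                state = "H"
            j -= 1

    if i > 0 and j > 0:  # pragma: no cover
        raise AssertionError("traceback did not reach an edge")
    overhang5 = i - j  # positive: query overhang, negative: ref overhang
    ops.reverse()
    return Alignment(
        query=query,
        ref=ref,
        score=score,
        ops="".join(ops),
        q_start=i,
        r_start=j,
        overhang5=overhang5 if free_head else 0,
        overhang3=overhang3,
    )


def _pick_end(H: np.ndarray, query: str, ref: str) -> tuple[int, int, int]:
    """End cell for overlap mode, per the documented tie-break rules."""
    L1 = len(query)
    L2 = len(ref)
    best = max(float(H[:, L2].max()), float(H[L1, :].max()))
    # candidates: (|overhang|, signed overhang, i, j)
    cands: list[tuple[int, int, int, int]] = []
    for i in range(L1, -1, -1):
        if H[i, L2] > best - _EPS:
            cands.append((L1 - i, L1 - i, i, L2))
    for j in range(L2, -1, -1):
        if H[L1, j] > best - _EPS:
            cands.append((L2 - j, -(L2 - j), L1, j))
    min_abs = min(c[0] for c in cands)
    cands = [c for c in cands if c[0] == min_abs]
    if len(cands) > 1 and min_abs > 0:
        # one query-side and one ref-side candidate of equal size: give the
        # overhang to the lexicographically greater sequence (antisymmetric)
        signed = min_abs if query > ref else -min_abs
        cands = [c for c in cands if c[1] == signed]
    _, signed, i, j = cands[0]
    return i, j, signed
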