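"""Independent reference implementations used only by the test suite.

These deliberately share no code with the package: plain-Python
dynamic programming with explicit loops, against which the vectorised
aligner and the demultiplexer are checked.
"""

from __future__ import annotations

NEG = float("-inf")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def gotoh_score(
    query: str,
    ref: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
    free_head: bool = False,
    free_tail: bool = False,
) -> float:
    """Optimal affine-gap alignment score by exhaustive DP.

    Same conventions as the package aligner (first gap column costs
    gap_open, later ones gap_extend; free ends as flagged) but written
    as straightforward nested loops over three explicit matrices.
    """
    n, m = len(query), len(ref)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (left)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (up)
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = max(E[0][j - 1] + gap_extend, H[0][j - 1] + gap_open)
        H[0][j] = 0.0 if free_head else E[0][j]
    for i in range(1, n + 1):
        F[i][0] = max(F[i - 1][0] + gap_extend, H[i - 1][0] + gap_open)
        H[i][0] = 0.0 if free_head else F[i][0]
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + gap_extend, H[i][j - 1] + gap_open)
            F[i][j] = max(F[i - 1][j] + gap_extend, H[i - 1][j] + gap_open)
            s = match if query[i - 1] == ref[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    if not free_tail:
        return H[n][m]
    best = NEG
    for i in range(n + 1):
        best = max(best, H[i][m])
    for j in range(m + 1):
        best = max(best, H[n][j])
    return best


def score_alignment(
    aln,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
    head_free: bool = False,
) -> float:
    """Recompute the score of a traced alignment from its ops.

    Leading gaps excluded from ``ops`` are free by construction; when
    ``head_free`` is False the caller must not have stripped them.
    """
    total = 0.0
    prev = "M"
    for (qc, rc), op in zip(aln.columns(), aln.ops):
        if op == "M":
            total += match if qc == rc else mismatch
        else:
            total += gap_extend if op == prev else gap_open
        prev = op
    return total


def hamming_prefix(pattern: str, prefix: str) -> int | None:
    """Substitution-only distance of an IUPAC pattern against a read
    start; None if the read is too short."""
    if len(prefix) < len(pattern):
        return None
    return sum(b not in IUPAC.get(p, p) for p, b in zip(pattern, prefix))


def edit_prefix(pattern: str, text: str) -> int:
    """Minimum edit distance of an IUPAC pattern against any prefix of
    ``text`` (start-anchored), by full Levenshtein DP."""
    n, m = len(pattern), len(text)
    prev = list(range(0, m + 1))
    # anchored at start: deleting text characters before the pattern is
    # not allowed, so row 0 is 0..m? -- no: row 0 cost j means skipping
    # j text chars, which un-anchors the match; anchored means row 0
    # costs grow with j
    prev = [j for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            sub = prev[j - 1] + (0 if text[j - 1] in IUPAC.get(pattern[i - 1], pattern[i - 1]) else 1)
            cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)  # free tail: pattern may end before the text does


def sliding_window_cut(qualities, window: int, mean_q: float) -> int | None:
    """First position (0-based) where a length-``window`` window's mean
    quality drops below ``mean_q``; None if no such window."""
    if window > len(qualities) or window <= 0:
        return None
    for start in range(len(qualities) - window + 1):
        if sum(qualities[start : start + window]) / window < mean_q:
            return start
    return None
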