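"""Seeded sequence-level synthetic cohorts for auditing the quantifier.

These generators complement the flowgram simulator: they produce
stage-pair and stage-triple read sets with *known* per-read edits, so
that change quantification, accordion diagnostics and positional
profiles can be checked against an exact ground truth.

Injected edits are kept well separated (and away from the read ends)
so that the optimal strict alignment recovers exactly the injected
counts; closely spaced insertion/deletion pairs would instead be
scored as substitution runs, which is a property of optimal alignment
itself, not of any particular aligner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_BASES = "ACGT"

#: minimum spacing between injected edits; large enough that a strict
#: aligner (high gap opening) never trades two distant gaps for a
#: mismatch run
_MIN_EDIT_SPACING = 60
_END_MARGIN = 10


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[int(rng.integers(3))]


@dataclass
class EditTruth:
    """Injected edits for one read."""

    read_id: str
    subs: int
    ins_bp: int
    del_bp: int
    ins_events: int
    del_events: int
    gap3: int


def apply_edits(
    seq: str,
    rng: np.random.Generator,
    n_sub: int = 0,
    n_ins: int = 0,
    n_del: int = 0,
    ins_len: int = 1,
    del_len: int = 1,
    trunc3: int = 0,
) -> tuple[str, EditTruth]:
    """Apply a known set of edits to ``seq`` and return the truth.

    Edits are placed at interior positions separated by at least
    ``_MIN_EDIT_SPACING`` bases and clear of the (possibly truncated)
    3' end.  Inserted bases are chosen to differ from both neighbours
    so the gap run cannot merge into an adjacent homopolymer ambiguity.
    """
    n_edits = n_sub + n_ins + n_del
    usable = len(seq) - trunc3 - 2 * _END_MARGIN
    if n_edits * _MIN_EDIT_SPACING > usable:
        raise ValueError(
            f"sequence of length {len(seq)} too short for {n_edits} edits "
            f"with spacing {_MIN_EDIT_SPACING} (truncation {trunc3})"
        )
    # choose ordered, well-separated positions
    slack = usable - n_edits * _MIN_EDIT_SPACING
    offsets = np.sort(rng.integers(0, slack + 1, size=n_edits)) if n_edits else np.array([], dtype=int)
    positions = [
        _END_MARGIN + int(off) + k * _MIN_EDIT_SPACING for k, off in enumerate(offsets)
    ]
    kinds = ["sub"] * n_sub + ["ins"] * n_ins + ["del"] * n_del
    rng.shuffle(kinds)

    out = list(seq)
    # apply right-to-left so earlier positions stay valid
    for pos, kind in sorted(zip(positions, kinds), reverse=True):
        if kind == "sub":
            out[pos] = _other_base(rng, out[pos])
        elif kind == "del":
            del out[pos : pos + del_len]
        else:
            left = out[pos - 1]
            right = out[pos]
            segment: list[str] = []
            for k in range(ins_len):
                avoid = {segment[-1] if segment else left}
                if k == ins_len - 1:
                    avoid.add(right)
                choices = [b for b in _BASES if b not in avoid]
                segment.append(choices[int(rng.integers(len(choices)))])
            out[pos:pos] = segment
    edited = "".join(out)
    if trunc3:
        edited = edited[:-trunc3]
    truth = EditTruth(
        read_id="",
        subs=n_sub,
        ins_bp=n_ins * ins_len,
        del_bp=n_del * del_len,
        ins_events=n_ins,
        del_events=n_del,
        gap3=-trunc3,
    )
    return edited, truth


def simulate_stage_pair(
    n_reads: int = 100,
    length: int = 400,
    sub_rate: float = 0.5,
    ins_rate: float = 0.3,
    del_rate: float = 0.3,
    ins_len: int = 1,
    del_len: int = 1,
    max_trunc3: int = 0,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """A (query, reference, truth) stage pair with injected edits.

    Rates are per-read probabilities of carrying one edit of each kind
    (a read can carry several kinds at once, always well separated).
    With ``max_trunc3`` > 0 each read is additionally 3'-truncated by a
    uniform 0..max_trunc3 bases (a negative 3' gap), as a filtering
    stage would.
    """
    rng = np.random.default_rng(seed)
    ref: dict[str, str] = {}
    query: dict[str, str] = {}
    rows = []
    for i in range(n_reads):
        rid = f"R{i:05d}"
        seq = random_sequence(rng, length)
        trunc = int(rng.integers(0, max_trunc3 + 1)) if max_trunc3 else 0
        edited, truth = apply_edits(
            seq,
            rng,
            n_sub=int(rng.random() < sub_rate),
            n_ins=int(rng.random() < ins_rate),
            n_del=int(rng.random() < del_rate),
            ins_len=ins_len,
            del_len=del_len,
            trunc3=trunc,
        )
        ref[rid] = seq
        query[rid] = edited
        rows.append(
            {
                "read_id": rid,
                "subs": truth.subs,
                "ins_bp": truth.ins_bp,
                "del_bp": truth.del_bp,
                "ins_events": truth.ins_events,
                "del_events": truth.del_events,
                "gap3": truth.gap3,
            }
        )
    truth_df = pd.DataFrame(rows, columns=["read_id", "subs", "ins_bp", "del_bp", "ins_events", "del_events", "gap3"])
    return query, ref, truth_df


def accordion_cohort(
    n_reads: int = 50,
    length: int = 300,
    min_trunc: int = 20,
    max_trunc: int = 60,
    tail_mut_frac: float = 0.3,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], dict[str, str], pd.DataFrame]:
    """A truncate-then-extend stage triple exhibiting the accordion effect.

    Stage 0: random reads.  Stage 1: each read 3'-truncated by a
    per-read number of bases (as a flowgram filter would).  Stage 2:
    each read re-extended to its original length, but with the re-added
    tail differing from the removed one at a fraction
    ``tail_mut_frac`` of its positions (a cluster representative's tail
    is rarely the read's own).  The truth table records each read's
    truncation length and the number of mismatching tail bases — the
    accordion excess.
    """
    rng = np.random.default_rng(seed)
    stage0: dict[str, str] = {}
    stage1: dict[str, str] = {}
    stage2: dict[str, str] = {}
    rows = []
    for i in range(n_reads):
        rid = f"A{i:05d}"
        seq = random_sequence(rng, length)
        k = int(rng.integers(min_trunc, max_trunc + 1))
        tail = list(seq[-k:])
        n_mut = max(1, int(round(tail_mut_frac * k)))
        mut_pos = rng.choice(k, size=n_mut, replace=False)
        for pos in mut_pos:
            tail[pos] = _other_base(rng, tail[pos])
        stage0[rid] = seq
        stage1[rid] = seq[:-k]
        stage2[rid] = seq[:-k] + "".join(tail)
        rows.append({"read_id": rid, "trunc_len": k, "tail_mismatches": n_mut, "trunc_point": length - k})
    truth = pd.DataFrame(rows, columns=["read_id", "trunc_len", "tail_mismatches", "trunc_point"])
    return stage0, stage1, stage2, truth
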