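"""Quantify the changes a pipeline stage makes to each read.

For every read the comparison runs in two phases:

1. an end-gap-tolerant global alignment with a low gap-opening penalty
   finds the signed 3' overhang between the stage's version of the read
   (query) and the earlier stage's version (reference).  This *3' gap*
   — bases added to (positive) or removed from (negative) the query's
   3' end — is recorded and the overhanging bases are removed from the
   longer sequence;
2. a strict global alignment (high gap-opening penalty) of the trimmed
   pair classifies every column as a match, substitution, insertion
   (query-only base) or deletion (reference-only base).  Insertions and
   deletions are counted both in base pairs and in *events* (maximal
   gap runs).

Aggregating the per-read records over a stage pair yields the familiar
stage table (read count, mean and SD of the 3' gap, substitution /
insertion / deletion totals, grand total), and comparing a chain of
stage tables exposes the *accordion effect*: truncating reads in one
step and re-lengthening them in the next inflates the net change count
beyond the sum of the steps whenever the re-added 3' bases differ from
those removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from flowaudit._align import Alignment, align, compatible


@dataclass
class AlignParams:
    """Scoring for the two alignment phases.

    ``end_*`` parameters drive the end-gap-tolerant phase.  Its end
    tolerance comes from the alignment mode itself — the 3' end is
    free outright — not from cheap internal gaps: by default internal
    gaps are as expensive as in the core phase, because a cheaply
    opened internal gap lets a luckily-matching +-1 shift of a
    divergent 3' tail outscore the true pairing and skew the overhang
    by a base.  ``core_*`` parameters drive the strict phase (large
    gap opening so gaps appear only when the trimmed lengths force
    them).  Constraint:
    ``gap_open <= gap_extend <= 0`` in both phases, which keeps the
    optimum deterministic under the fixed tie-break order.

    With ``iupac_tolerant`` a column pairing a degenerate code with one
    of its member bases is not counted as a difference (used when reads
    still carry a degenerate primer base).
    """

    match: float = 5.0
    mismatch: float = -4.0
    end_gap_open: float = -100.0
    end_gap_extend: float = -1.0
    core_gap_open: float = -100.0
    core_gap_extend: float = -1.0
    iupac_tolerant: bool = False

    def __post_init__(self) -> None:
        for open_, ext in ((self.end_gap_open, self.end_gap_extend), (self.core_gap_open, self.core_gap_extend)):
            if not (open_ <= ext <= 0):
                raise ValueError("gap penalties must satisfy gap_open <= gap_extend <= 0")
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")


@dataclass
class ChangeRecord:
    """Per-read change counts between two pipeline stages.

    ``gap3`` is signed: positive bases were added at the query 3' end,
    negative were removed.  A non-zero ``gap5`` (5' overhang) indicates
    a prefix-handling problem upstream and is reported separately,
    never folded into ``gap3``.
    """

    read_id: str
    gap3: int
    subs: int
    ins_bp: int
    del_bp: int
    ins_events: int
    del_events: int
    gap5: int = 0
    alignment: Alignment | None = field(default=None, repr=False, compare=False)
    query_offset: int = field(default=0, repr=False, compare=False)

    def __post_init__(self) -> None:
        if min(self.subs, self.ins_bp, self.del_bp, self.ins_events, self.del_events) < 0:
            raise ValueError(f"{self.read_id}: change counts must be >= 0")
        if self.ins_events > self.ins_bp or self.del_events > self.del_bp:
            raise ValueError(f"{self.read_id}: events cannot exceed base-pair counts")

    @property
    def total(self) -> int:
        return self.subs + self.ins_bp + self.del_bp


@dataclass
class ChangeTable:
    """A set of per-read change records plus their aggregate."""

    records: list[ChangeRecord]
    eliminated: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> set[str]:
        return {rec.read_id for rec in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "read_id": r.read_id,
                    "gap3": r.gap3,
                    "gap5": r.gap5,
                    "subs": r.subs,
                    "ins_bp": r.ins_bp,
                    "ins_events": r.ins_events,
                    "del_bp": r.del_bp,
                    "del_events": r.del_events,
                    "total": r.total,
                }
                for r in self.records
            ],
            columns=["read_id", "gap3", "gap5", "subs", "ins_bp", "ins_events", "del_bp", "del_events", "total"],
        )

    def summary(self) -> pd.DataFrame:
        """One row in stage-table order: reads analyzed, mean (SD) 3'
        gap, substitution / insertion / deletion totals (bp), total."""
        gap3 = np.array([r.gap3 for r in self.records], dtype=float)
        subs = sum(r.subs for r in self.records)
        ins = sum(r.ins_bp for r in self.records)
        dels = sum(r.del_bp for r in self.records)
        return pd.DataFrame(
            [
                {
                    "reads": len(self.records),
                    "mean_gap3": float(gap3.mean()) if len(gap3) else 0.0,
                    "sd_gap3": float(gap3.std(ddof=1)) if len(gap3) > 1 else 0.0,
                    "substitutions": subs,
                    "insertions": ins,
                    "deletions": dels,
                    "total_changes": subs + ins + dels,
                }
            ]
        )

    def totals(self) -> dict[str, float]:
        row = self.summary().iloc[0]
        return {k: (float(v) if "gap3" in k else int(v)) for k, v in row.items()}


def quantify_pair(
    query: str,
    ref: str,
    p: AlignParams | None = None,
    read_id: str = "",
    keep_alignment: bool = False,
) -> ChangeRecord:
    """Change record for one read between two stages.

    ``query`` is the later stage's version of the read, ``ref`` the
    earlier one.
    """
    p = p or AlignParams()
    if not query or not ref:
        raise ValueError(f"{read_id or 'read'}: cannot quantify an empty sequence")
    query = query.upper()
    ref = ref.upper()

    # 5'-anchored, 3'-free: reads share their 5' start across stages, so
    # leading gaps are penalised (cheaply) and only the 3' end is free —
    # this pins down the overhang even for periodic sequences.  A leading
    # gap run that survives anyway is a 5' anomaly, reported as gap5.
    phase1 = align(
        query,
        ref,
        match=p.match,
        mismatch=p.mismatch,
        gap_open=p.end_gap_open,
        gap_extend=p.end_gap_extend,
        free_tail=True,
        iupac_tolerant=p.iupac_tolerant,
    )
    gap3 = phase1.overhang3
    lead_i = len(phase1.ops) - len(phase1.ops.lstrip("I"))
    lead_d = len(phase1.ops) - len(phase1.ops.lstrip("D"))
    gap5 = lead_i if lead_i else -lead_d

    q2, r2 = query, ref
    if gap3 > 0:
        q2 = q2[: len(q2) - gap3]
    elif gap3 < 0:
        r2 = r2[: len(r2) + gap3]
    offset = 0
    if gap5 > 0:
        q2 = q2[gap5:]
        offset = gap5
    elif gap5 < 0:
        r2 = r2[-gap5:]

    if not q2 or not r2:
        # the overhang consumed a whole sequence; nothing aligned remains
        return ChangeRecord(read_id, gap3, 0, 0, 0, 0, 0, gap5=gap5)

    phase2 = align(
        q2,
        r2,
        match=p.match,
        mismatch=p.mismatch,
        gap_open=p.core_gap_open,
        gap_extend=p.core_gap_extend,
        iupac_tolerant=p.iupac_tolerant,
    )
    subs, ins_bp, del_bp, ins_ev, del_ev = classify_columns(phase2, p.iupac_tolerant)
    return ChangeRecord(
        read_id,
        gap3,
        subs,
        ins_bp,
        del_bp,
        ins_ev,
        del_ev,
        gap5=gap5,
        alignment=phase2 if keep_alignment else None,
        query_offset=offset,
    )


def classify_columns(aln: Alignment, iupac_tolerant: bool) -> tuple[int, int, int, int, int]:
    """(subs, ins_bp, del_bp, ins_events, del_events) for an alignment."""
    subs = ins_bp = del_bp = ins_ev = del_ev = 0
    prev = "M"
    for (qc, rc), op in zip(aln.columns(), aln.ops):
        if op == "M":
            same = compatible(qc, rc) if iupac_tolerant else (qc == rc)
            if not same:
                subs += 1
        elif op == "I":
            ins_bp += 1
            if prev != "I":
                ins_ev += 1
        else:
            del_bp += 1
            if prev != "D":
                del_ev += 1
        prev = op
    return subs, ins_bp, del_bp, ins_ev, del_ev


def _as_mapping(source) -> dict[str, str]:
    if isinstance(source, Mapping):
        return {str(k): str(v) for k, v in source.items()}
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(source), "fasta")}


def quantify_set(
    query: Mapping[str, str] | str | Path,
    ref: Mapping[str, str] | str | Path,
    p: AlignParams | None = None,
    keep_alignments: bool = False,
) -> ChangeTable:
    """Change table between two stages given as FASTA paths or id->seq maps.

    Every query id must exist in the reference set; ids present only in
    the reference are listed as eliminated at this stage and excluded
    from the change totals.
    """
    p = p or AlignParams()
    qmap = _as_mapping(query)
    rmap = _as_mapping(ref)
    missing = sorted(set(qmap) - set(rmap))
    if missing:
        shown = ", ".join(missing[:10]) + ("..." if len(missing) > 10 else "")
        raise KeyError(f"{len(missing)} query id(s) missing from reference: {shown}")
    records = [
        quantify_pair(qmap[rid], rmap[rid], p, read_id=rid, keep_alignment=keep_alignments)
        for rid in qmap
    ]
    eliminated = sorted(set(rmap) - set(qmap))
    return ChangeTable(records=records, eliminated=eliminated)


def accordion_report(
    table_0_to_1: ChangeTable,
    table_1_to_2: ChangeTable,
    table_0_to_2: ChangeTable,
) -> pd.DataFrame:
    """Net-versus-sum comparison over a truncate-then-cluster stage triple.

    For each change category the report gives the sum of the two step
    totals, the net (first-to-last) total, and the excess.  The
    accordion effect is flagged when the net total of changes exceeds
    the sum of the step totals: the bases re-added at the 3' end in the
    second step were not the bases removed in the first.
    """
    ids = table_0_to_2.ids()
    if table_0_to_1.ids() != ids or table_1_to_2.ids() != ids:
        raise ValueError("accordion comparison requires identical read sets in all three tables")
    cats = ["substitutions", "insertions", "deletions", "total_changes"]
    t01 = table_0_to_1.summary().iloc[0]
    t12 = table_1_to_2.summary().iloc[0]
    t02 = table_0_to_2.summary().iloc[0]
    rows = []
    for cat in cats:
        step_sum = int(t01[cat] + t12[cat])
        net = int(t02[cat])
        rows.append(
            {
                "category": cat,
                "step_sum": step_sum,
                "net": net,
                "excess": net - step_sum,
                "accordion": net > step_sum,
            }
        )
    return pd.DataFrame(rows, columns=["category", "step_sum", "net", "excess", "accordion"])


def positional_profile(
    records: Iterable[ChangeRecord],
    iupac_tolerant: bool = False,
) -> pd.DataFrame:
    """Per-position change counts along the query reads (1-based).

    Substitutions and insertions are counted at the query position of
    the changed base; deletion events at the query position before
    which the missing bases would sit.  Records must have been produced
    with ``keep_alignment(s)=True``; pass the same ``iupac_tolerant``
    setting that produced them.
    """
    from collections import defaultdict

    subs: dict[int, int] = defaultdict(int)
    ins: dict[int, int] = defaultdict(int)
    dels: dict[int, int] = defaultdict(int)
    for rec in records:
        if rec.alignment is None:
            raise ValueError(f"{rec.read_id}: record carries no alignment (use keep_alignments=True)")
        pos = rec.query_offset  # 0-based count of consumed query bases
        prev = "M"
        for (qc, rc), op in zip(rec.alignment.columns(), rec.alignment.ops):
            if op == "M":
                pos += 1
                same = compatible(qc, rc) if iupac_tolerant else (qc == rc)
                if not same:
                    subs[pos] += 1
            elif op == "I":
                pos += 1
                ins[pos] += 1
            else:
                if prev != "D":
                    dels[pos + 1] += 1
            prev = op
    positions = sorted(set(subs) | set(ins) | set(dels))
    return pd.DataFrame(
        [
            {
                "position": p,
                "substitutions": subs.get(p, 0),
                "insertions": ins.get(p, 0),
                "deletions": dels.get(p, 0),
                "total": subs.get(p, 0) + ins.get(p, 0) + dels.get(p, 0),
            }
            for p in positions
        ],
        columns=["position", "substitutions", "insertions", "deletions", "total"],
    )


def length_summary(stages: Mapping[str, Mapping[str, str] | str | Path]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read-length distributions and total sequence information per stage.

    Returns ``(summary, histogram)``: the summary has one row per stage
    (read count, total bases — the area under the length curve — and
    mean length); the histogram has one row per (stage, length).
    """
    summary_rows = []
    hist_rows = []
    for label, source in stages.items():
        seqs = _as_mapping(source)
        lengths = pd.Series([len(s) for s in seqs.values()], dtype=int)
        summary_rows.append(
            {
                "stage": label,
                "reads": len(lengths),
                "total_bases": int(lengths.sum()) if len(lengths) else 0,
                "mean_length": float(lengths.mean()) if len(lengths) else 0.0,
            }
        )
        for length, count in lengths.value_counts().sort_index().items():
            hist_rows.append({"stage": label, "length": int(length), "count": int(count)})
    return (
        pd.DataFrame(summary_rows, columns=["stage", "reads", "total_bases", "mean_length"]),
        pd.DataFrame(hist_rows, columns=["stage", "length", "count"]),
    )
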