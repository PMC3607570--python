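"""Assign reads to sample bins by mid tag + primer.

Each sequencing library prefixes every read with a 25 bp adaptor, a
10-11 bp multiplex identifier (mid) tag unique per sample, and one of
the PCR primers (which may contain IUPAC degenerate codes).  Exact-mode
matching mirrors the strict behaviour of the original splitter scripts
(a read is binned only if its prefix equals mid+primer literally, with
degenerate primer codes matching their member bases at no cost); the
tolerant mode budgets mismatches and single-base indels jointly as an
edit distance, which reproduces the "single mismatch or in/del"
experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import edlib
import pandas as pd

from flowaudit.flowgram_io import FlowgramSet

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: edlib equality pairs letting degenerate codes match their members for free
_IUPAC_EQUALITIES = [
    (code, base) for code, members in IUPAC.items() if len(members) > 1 for base in members
]


@dataclass(frozen=True)
class SampleKey:
    """One demultiplexing key: a (sample, primer) bin.

    ``adaptor_len`` leading bases are skipped before matching (25 for
    the standard library construction; 0 for synthetic reads without an
    adaptor).
    """

    sample_id: str
    mid_tag: str
    primer_name: str
    primer_seq: str
    adaptor_len: int = 0

    def __post_init__(self) -> None:
        if len(self.mid_tag) not in (10, 11):
            raise ValueError(
                f"{self.sample_id}: mid tag must be 10-11 bp, got {len(self.mid_tag)}"
            )
        if not self.primer_seq:
            raise ValueError(f"{self.sample_id}: primer must be non-empty")

    @property
    def bin_id(self) -> str:
        return f"{self.sample_id}.{self.primer_name}" if self.primer_name else self.sample_id

    @property
    def pattern(self) -> str:
        return self.mid_tag + self.primer_seq


def load_key_table(path: str | Path, adaptor_len: int = 0) -> list[SampleKey]:
    """Load a sample key table from CSV.

    Expected columns: ``sample_id``, ``mid_tag``, ``primer_name``,
    ``primer_seq``.  When a sample's mid tag is shared across several
    primers, each (sample, primer) pair becomes its own bin.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sample_id", "mid_tag", "primer_name", "primer_seq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"key table missing columns: {sorted(missing)}")
    keys = [
        SampleKey(
            sample_id=row.sample_id,
            mid_tag=row.mid_tag,
            primer_name=row.primer_name,
            primer_seq=row.primer_seq,
            adaptor_len=adaptor_len,
        )
        for row in df.itertuples()
    ]
    validate_keys(keys)
    return keys


def validate_keys(keys: list[SampleKey]) -> None:
    if not keys:
        raise ValueError("empty key table")
    seen: set[tuple[str, str]] = set()
    for key in keys:
        pair = (key.mid_tag, key.primer_seq)
        if pair in seen:
            raise ValueError(f"duplicate (mid_tag, primer) pair: {pair}")
        seen.add(pair)


def _iupac_exact(pattern: str, prefix: str) -> bool:
    """Literal match where degenerate codes in the pattern match any of
    their member bases at no cost."""
    if len(prefix) < len(pattern):
        return False
    return all(b in IUPAC.get(p, p) for p, b in zip(pattern, prefix))


@dataclass(frozen=True)
class Assignment:
    """Result of matching one read against a key table."""

    key: SampleKey | None
    distance: int | None
    reason: str  # "assigned" | "no_match" | "ambiguous" | "too_short"

    @property
    def assigned(self) -> bool:
        return self.key is not None


def match_key(
    read_prefix: str,
    keys: list[SampleKey],
    max_mismatch: int = 0,
    allow_indel: bool = False,
) -> Assignment:
    """Match a read's 5' sequence against the key table.

    With ``max_mismatch=0`` and ``allow_indel=False`` the assignment
    requires the prefix to literally equal mid_tag + primer (IUPAC
    degeneracy in the primer is free); longer mid tags are tried first.
    Otherwise the unique key whose pattern matches the start of the
    read within the edit budget wins; ties at the best distance between
    different keys leave the read unassigned as "ambiguous".
    """
    validate_keys(keys)
    ordered = sorted(keys, key=lambda k: (-len(k.mid_tag), k.bin_id))
    exact = max_mismatch == 0 and not allow_indel
    if exact:
        for key in ordered:
            prefix = read_prefix[key.adaptor_len:]
            if len(prefix) < len(key.pattern):
                continue
            if _iupac_exact(key.pattern, prefix):
                return Assignment(key, 0, "assigned")
        return Assignment(None, None, "no_match")

    budget = max(max_mismatch, 1 if allow_indel else 0)
    best: list[tuple[int, SampleKey]] = []
    for key in ordered:
        if allow_indel:
            prefix = read_prefix[key.adaptor_len : key.adaptor_len + len(key.pattern) + budget]
            if not prefix:
                continue
            res = edlib.align(
                key.pattern,
                prefix,
                mode="SHW",  # pattern anchored at the prefix start, free tail
                k=budget,
                additionalEqualities=_IUPAC_EQUALITIES,
            )
            dist = res["editDistance"]
            if dist < 0:
                continue
        else:
            # substitution-only budget: Hamming over the pattern length
            d = _hamming_iupac(key.pattern, read_prefix[key.adaptor_len:])
            if d is None or d > budget:
                continue
            dist = d
        best.append((dist, key))
    if not best:
        return Assignment(None, None, "no_match")
    best.sort(key=lambda t: (t[0], -len(t[1].mid_tag), t[1].bin_id))
    top_dist = best[0][0]
    top = [key for d, key in best if d == top_dist]
    if len(top) > 1:
        return Assignment(None, top_dist, "ambiguous")
    return Assignment(top[0], top_dist, "assigned")


def _hamming_iupac(pattern: str, prefix: str) -> int | None:
    if len(prefix) < len(pattern):
        return None
    return sum(b not in IUPAC.get(p, p) for p, b in zip(pattern, prefix))


def split_flowgrams(
    fset: FlowgramSet,
    keys: list[SampleKey],
    max_mismatch: int = 0,
    allow_indel: bool = False,
) -> tuple[dict[str, FlowgramSet], FlowgramSet, pd.DataFrame]:
    """Partition a flowgram set into per-(sample, primer) bins.

    Matching operates on the instrument base call.  Every read lands in
    exactly one bin or in the unassigned set; per-bin counts are
    returned as a DataFrame (``bin``, ``count``), with unassigned reads
    broken out by reason.
    """
    validate_keys(keys)
    bins: dict[str, FlowgramSet] = {key.bin_id: FlowgramSet(fset.flow_order) for key in keys}
    unassigned = FlowgramSet(fset.flow_order)
    counts: dict[str, int] = dict.fromkeys(list(bins) + ["unassigned:no_match", "unassigned:ambiguous", "unassigned:no_call"], 0)
    for fg in fset:
        if not fg.called_bases:
            unassigned.append(fg)
            counts["unassigned:no_call"] += 1
            continue
        result = match_key(fg.called_bases, keys, max_mismatch=max_mismatch, allow_indel=allow_indel)
        if result.assigned:
            bins[result.key.bin_id].append(fg)
            counts[result.key.bin_id] += 1
        else:
            unassigned.append(fg)
            counts[f"unassigned:{result.reason}"] += 1
    report = pd.DataFrame({"bin": list(counts), "count": list(counts.values())})
    return bins, unassigned, report
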