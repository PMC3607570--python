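"""Rebuild the full read set at any pipeline stage.

Denoisers output a mapping of reads to clusters plus one representative
sequence per cluster.  To audit what the denoiser did to *reads*, every
member read is expanded to its cluster's representative sequence, and
— at stages where the pipeline had stripped them — the mid tag (and
optionally primer) is reattached so that stage-to-stage comparisons run
in the same coordinates.

The canonical cluster-map dialect is a two-column TSV (read_id,
cluster_id) plus a representative FASTA; thin importers convert the
common denoiser output layouts into it.  Representative choice is an
input, never recomputed: the toolkit audits the denoiser's choice.  A
diagnostic flags clusters whose representative is the longest member,
the mechanism behind 3'-end lengthening of truncated reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from flowaudit.demux import SampleKey


@dataclass
class ClusterMap:
    """read_id -> cluster_id assignments plus per-cluster representatives."""

    assignments: dict[str, str]
    representatives: dict[str, str]

    def __post_init__(self) -> None:
        missing = sorted({c for c in self.assignments.values() if c not in self.representatives})
        if missing:
            shown = ", ".join(missing[:10]) + ("..." if len(missing) > 10 else "")
            raise ValueError(f"clusters without a representative: {shown}")

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(list(self.assignments.values())).value_counts()


def load_cluster_map(mapping_tsv: str | Path, rep_fasta: str | Path) -> ClusterMap:
    """Load the canonical dialect: TSV (read_id, cluster_id) + FASTA."""
    assignments: dict[str, str] = {}
    with open(mapping_tsv) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{mapping_tsv}: line {lineno}: expected 2 columns, got {len(parts)}")
            read_id, cluster_id = parts
            if read_id in assignments:
                raise ValueError(f"{mapping_tsv}: read {read_id!r} assigned more than once")
            assignments[read_id] = cluster_id
    reps = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(rep_fasta), "fasta")}
    return ClusterMap(assignments=assignments, representatives=reps)


def import_names_file(path: str | Path) -> dict[str, str]:
    """mothur name-file layout: ``rep_id<TAB>id1,id2,...`` per cluster;
    the representative's id doubles as the cluster id."""
    assignments: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rep, members = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated fields") from exc
            for read_id in members.split(","):
                if read_id in assignments:
                    raise ValueError(f"{path}: read {read_id!r} assigned more than once")
                assignments[read_id] = rep
    return assignments


def import_ampnoise_mapping(path: str | Path) -> dict[str, str]:
    """Flowgram-clustering mapping layout: one cluster per line, the
    cluster id first, then its member read ids (whitespace-separated)."""
    assignments: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            tokens = line.split()
            if not tokens:
                continue
            cluster_id, *members = tokens
            if not members:
                raise ValueError(f"{path}: line {lineno}: cluster {cluster_id!r} has no members")
            for read_id in members:
                if read_id in assignments:
                    raise ValueError(f"{path}: read {read_id!r} assigned more than once")
                assignments[read_id] = cluster_id
    return assignments


def import_denoiser_mapping(path: str | Path) -> dict[str, str]:
    """QIIME denoiser mapping layout: ``cluster_id:<TAB>member...``; the
    cluster id (its centroid read) is itself a member."""
    assignments: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line:
                continue
            head, *members = line.split("\t")
            cluster_id = head.rstrip(":")
            for read_id in [cluster_id, *members]:
                if read_id in assignments and assignments[read_id] != cluster_id:
                    raise ValueError(f"{path}: read {read_id!r} assigned more than once")
                assignments[read_id] = cluster_id
    return assignments


def expand_clusters(cmap: ClusterMap) -> dict[str, str]:
    """One sequence per assigned read: its cluster's representative."""
    out: dict[str, str] = {}
    for read_id, cluster_id in cmap.assignments.items():
        try:
            out[read_id] = cmap.representatives[cluster_id]
        except KeyError as exc:  # pragma: no cover - guarded in __post_init__
            raise KeyError(f"read {read_id!r} mapped to unknown cluster {cluster_id!r}") from exc
    return out


def longest_member_diagnostic(cmap: ClusterMap, member_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Flag clusters whose representative is as long as their longest member.

    Picking the longest read as a cluster's representative is what adds
    3' bases to every shorter member on expansion.
    """
    rows = []
    by_cluster: dict[str, list[str]] = {}
    for read_id, cluster_id in cmap.assignments.items():
        by_cluster.setdefault(cluster_id, []).append(read_id)
    for cluster_id, members in sorted(by_cluster.items()):
        rep_len = len(cmap.representatives[cluster_id])
        longest = max(member_lengths[m] for m in members)
        rows.append(
            {
                "cluster_id": cluster_id,
                "size": len(members),
                "rep_length": rep_len,
                "longest_member": longest,
                "rep_is_longest": rep_len >= longest,
            }
        )
    return pd.DataFrame(rows, columns=["cluster_id", "size", "rep_length", "longest_member", "rep_is_longest"])


def reattach_prefix(
    reads: Mapping[str, str],
    keys: list[SampleKey],
    sample_of_read: Mapping[str, str],
    include_primer: bool = True,
) -> dict[str, str]:
    """Restore the mid tag (+ primer) at the 5' end of each read.

    ``sample_of_read`` maps read ids to the bin_id of a key.  Reattaching
    twice would forge prefix-doubled reads, so a read that already
    starts with its prefix is refused.
    """
    by_bin = {key.bin_id: key for key in keys}
    out: dict[str, str] = {}
    for read_id, seq in reads.items():
        sample = sample_of_read.get(read_id)
        if sample is None or sample not in by_bin:
            raise KeyError(f"read {read_id!r}: unknown sample {sample!r}")
        key = by_bin[sample]
        prefix = key.mid_tag + (key.primer_seq if include_primer else "")
        if seq.startswith(prefix):
            raise ValueError(
                f"read {read_id!r} already starts with its prefix {prefix!r}; refusing to reattach twice"
            )
        out[read_id] = prefix + seq
    return out


def strip_prefix(
    reads: Mapping[str, str],
    keys: list[SampleKey],
    sample_of_read: Mapping[str, str],
    include_primer: bool = True,
) -> dict[str, str]:
    """Inverse of :func:`reattach_prefix`."""
    by_bin = {key.bin_id: key for key in keys}
    out: dict[str, str] = {}
    for read_id, seq in reads.items():
        sample = sample_of_read.get(read_id)
        if sample is None or sample not in by_bin:
            raise KeyError(f"read {read_id!r}: unknown sample {sample!r}")
        key = by_bin[sample]
        prefix = key.mid_tag + (key.primer_seq if include_primer else "")
        if not seq.startswith(prefix):
            raise ValueError(f"read {read_id!r} does not start with its prefix {prefix!r}")
        out[read_id] = seq[len(prefix):]
    return out


def write_fasta(reads: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read_id, seq in reads.items():
            handle.write(f">{read_id}\n{seq}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
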