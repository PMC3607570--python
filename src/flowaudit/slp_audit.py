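"""Event-based pairwise distance and single-linkage preclustering audit.

Single-linkage preclustering (SLP) merges reads whose pairwise distance
is below a width parameter, measuring distance on an optimal global
alignment where *insertions and deletions of any size count as a single
event*:

    distance = (mismatches + indel events) /
               (matches + mismatches + indel events)

Terminal gap runs arising from length differences are excluded: two
reads identical over the shorter read's length are at distance 0.  This
is precisely what makes width-0 clustering able to link two divergent
long reads through a short read matching both perfectly — the
*chaining effect* this module diagnoses.  The ``center_only`` variant
admits a read only if it is within the width of the cluster's seed,
which bounds every member-center distance by the width and rules
chaining out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from flowaudit._align import Alignment, align
from flowaudit.change_quant import classify_columns

_log = logging.getLogger(__name__)


@dataclass
class SLPParams:
    """``width``: maximum pairwise distance for joining a cluster;
    ``mode``: ``any_member`` (true single linkage) or ``center_only``."""

    width: float = 0.02
    mode: str = "any_member"

    def __post_init__(self) -> None:
        if self.width < 0:
            raise ValueError("width must be >= 0")
        if self.mode not in ("any_member", "center_only"):
            raise ValueError(f"unknown mode {self.mode!r}")


def event_distance(a: str, b: str) -> float:
    """Pairwise distance where each maximal internal gap run counts once.

    The sequences are aligned *globally* (terminal gaps are penalised,
    so unrelated sequences cannot dodge comparison by overlapping on a
    few bases), but the terminal gap runs of the optimal alignment are
    then excluded from the count.  Symmetric; 0 iff the sequences align
    without mismatches or internal gaps — in particular, two reads
    identical over the shorter read's length are at distance 0.
    """
    if not a or not b:
        raise ValueError("cannot compute a distance involving an empty sequence")
    a, b = a.upper(), b.upper()
    if b < a:
        # canonical order: traceback tie-breaks are orientation-dependent,
        # and insertions/deletions count alike, so aligning the sorted
        # pair makes the distance exactly symmetric
        a, b = b, a
    aln = align(a, b)
    ops = aln.ops
    # strip the terminal gap runs: they reflect length difference only
    head = len(ops) - len(ops.lstrip("ID"))
    tail = len(ops) - len(ops.rstrip("ID"))
    trimmed = Alignment(
        query=aln.query,
        ref=aln.ref,
        score=aln.score,
        ops=ops[head : len(ops) - tail],
        q_start=ops[:head].count("I"),
        r_start=ops[:head].count("D"),
        overhang5=0,
        overhang3=0,
    )
    subs, ins_bp, del_bp, ins_ev, del_ev = classify_columns(trimmed, iupac_tolerant=False)
    matches = trimmed.ops.count("M") - subs
    events = ins_ev + del_ev
    if subs and events:
        # the documented worked example has one difference kind only; the
        # generalised numerator (mismatches + events together) is in use
        _log.debug("event_distance: %d mismatches and %d indel events co-occur", subs, events)
    denom = matches + subs + events
    if denom == 0:
        return 1.0  # nothing aligned at all
    return (subs + events) / denom


@dataclass
class Cluster:
    """An SLP cluster with join provenance.

    ``parent[m]`` is the member that admitted ``m`` (the seed for the
    ``center_only`` mode and for reads joined directly to the seed);
    ``depth[m]`` is the admission-chain length from the seed.
    """

    seed: str
    members: list[str] = field(default_factory=list)
    parent: dict[str, str] = field(default_factory=dict)
    depth: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def slp_cluster(
    reads: Mapping[str, str],
    abundances: Mapping[str, int] | None = None,
    p: SLPParams | None = None,
) -> list[Cluster]:
    """Greedy single-linkage preclustering.

    Reads are processed in decreasing abundance (ties broken by read
    id).  A read joins the first existing cluster (in creation order)
    that admits it — ``any_member``: within ``width`` of any member;
    ``center_only``: within ``width`` of the seed — and seeds a new
    cluster when none does.  Every read is assigned exactly once.
    """
    p = p or SLPParams()
    abundances = abundances or {}
    for rid, ab in abundances.items():
        if ab < 1:
            raise ValueError(f"{rid}: abundance must be >= 1")
    order = sorted(reads, key=lambda rid: (-abundances.get(rid, 1), rid))
    clusters: list[Cluster] = []
    cache: dict[tuple[str, str], float] = {}

    def dist(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key not in cache:
            cache[key] = event_distance(reads[x], reads[y])
        return cache[key]

    for rid in order:
        placed = False
        for cluster in clusters:
            if p.mode == "center_only":
                if dist(rid, cluster.seed) <= p.width:
                    cluster.members.append(rid)
                    cluster.parent[rid] = cluster.seed
                    cluster.depth[rid] = 1
                    placed = True
            else:
                for member in cluster.members:
                    if dist(rid, member) <= p.width:
                        cluster.members.append(rid)
                        cluster.parent[rid] = member
                        cluster.depth[rid] = cluster.depth[member] + 1
                        placed = True
                        break
            if placed:
                break
        if not placed:
            cluster = Cluster(seed=rid, members=[rid])
            cluster.parent[rid] = rid
            cluster.depth[rid] = 0
            clusters.append(cluster)
    return clusters


def chaining_depth(cluster: Cluster, reads: Mapping[str, str]) -> tuple[int, float]:
    """(max admission-chain depth, max member-to-seed event distance).

    In ``center_only`` clusters the second value never exceeds the
    width; in ``any_member`` clusters it can, which is the chaining
    diagnostic.
    """
    if not cluster.depth or set(cluster.depth) != set(cluster.members):
        raise ValueError(f"cluster {cluster.seed!r}: missing join provenance")
    max_depth = max(cluster.depth.values())
    max_dist = max(
        (event_distance(reads[m], reads[cluster.seed]) for m in cluster.members if m != cluster.seed),
        default=0.0,
    )
    return max_depth, max_dist


def clusters_to_map(clusters: list[Cluster], reads: Mapping[str, str]):
    """Convert SLP output to a :class:`~flowaudit.reconstitute.ClusterMap`
    whose representatives are the cluster seeds."""
    from flowaudit.reconstitute import ClusterMap

    assignments = {m: c.seed for c in clusters for m in c.members}
    representatives = {c.seed: reads[c.seed] for c in clusters}
    return ClusterMap(assignments=assignments, representatives=representatives)
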