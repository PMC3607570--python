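"""Flowgram and quality filtering, in the three styles the major 454
amplicon pipelines used.

* **framed** — the flowgram is inspected one frame of four flows
  (T-A-C-G) at a time and truncated before the first frame in which
  (1) all four values are below the no-signal threshold, (2) any value
  exceeds the large-flow ceiling, or (3) any value falls strictly
  inside the "noisy" interval (0.50, 0.70).  Because only one frame
  phase is inspected, a low-signal run that straddles a frame boundary
  is *not* detected — a documented blindness this module reproduces.

* **flowwise** — the same three criteria applied flow by flow:
  truncate before any flow that is (1) < 0.50 with the next two flows
  also <= 0.50, (2) above the large-flow ceiling, or (3) in
  [0.50, 0.70) — note the closed lower bound, unlike the framed
  family.  A no-truncate variant applies only the minimum-flows test.

* **quality window** — sliding-window mean quality truncation with
  length bounds, as in amplicon library splitters.

After any truncation, a read is eliminated when fewer than
``min_flows`` remain, and truncated to ``max_flows`` when more remain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from flowaudit.flowgram_io import Flowgram

_log = logging.getLogger(__name__)

REASONS = ("no_signal_run", "large_flow", "noisy_flow", "too_few_flows", "too_many_flows", "none")


@dataclass
class FilterParams:
    """Thresholds shared by the flowgram filter families.

    Defaults follow the frame-of-four filter: no-signal below 0.50,
    noisy interval 0.50–0.70, large-flow ceiling 6.49 (an alternate
    convention uses 9.49), minimum 360 flows, truncation ceiling 720.
    The mothur-style variant uses min_flows = max_flows = 450.
    """

    low_signal: float = 0.50
    noisy_lo: float = 0.50
    noisy_hi: float = 0.70
    large_flow: float = 6.49
    min_flows: int = 360
    max_flows: int = 720

    def __post_init__(self) -> None:
        if not (0 <= self.low_signal <= self.noisy_lo < self.noisy_hi <= self.large_flow):
            raise ValueError(
                "thresholds must satisfy 0 <= low_signal <= noisy_lo < noisy_hi <= large_flow"
            )
        if self.min_flows > self.max_flows:
            raise ValueError("min_flows must be <= max_flows")

    @classmethod
    def mothur_defaults(cls) -> "FilterParams":
        return cls(min_flows=450, max_flows=450)


@dataclass
class FilterOutcome:
    """Per-read filtering verdict.

    ``status`` is ``retained`` or ``eliminated``; elimination is always
    the post-truncation length test, so the criterion that *caused* a
    truncation is recorded separately in ``trunc_reason`` while
    ``reason`` carries the first-triggered criterion overall (the
    truncation trigger if any, else the length test, else ``none``).
    """

    read_id: str
    status: str
    kept_flows: int
    reason: str
    trunc_reason: str = "none"

    def __post_init__(self) -> None:
        if self.status not in ("retained", "eliminated"):
            raise ValueError(f"bad status {self.status!r}")
        if self.reason not in REASONS or self.trunc_reason not in REASONS:
            raise ValueError(f"bad reason {self.reason!r}/{self.trunc_reason!r}")

    @property
    def truncated(self) -> bool:
        return self.trunc_reason != "none"


def _finalize(fg: Flowgram, cut: int | None, trunc_reason: str, p: FilterParams) -> tuple[FilterOutcome, Flowgram]:
    """Apply the min/max flow bookkeeping shared by both flowgram families."""
    remaining = cut if cut is not None else fg.usable_flows
    if remaining < p.min_flows:
        out = FilterOutcome(fg.read_id, "eliminated", remaining, "too_few_flows", trunc_reason)
        return out, fg.truncated(remaining)
    if remaining > p.max_flows:
        remaining = p.max_flows
        if trunc_reason == "none":
            trunc_reason = "too_many_flows"
    if remaining != fg.usable_flows or cut is not None:
        truncated = fg.truncated(remaining)
    else:
        truncated = fg
    reason = trunc_reason
    out = FilterOutcome(fg.read_id, "retained", remaining, reason, trunc_reason)
    return out, truncated


def framed_filter(fg: Flowgram, p: FilterParams | None = None) -> tuple[FilterOutcome, Flowgram]:
    """Frame-of-four flowgram filter.

    Scans whole frames within the first ``usable_flows`` flows; the
    truncation point is always a multiple of the cycle length.  A final
    partial frame is ignored.  Criterion 3 uses the strict interval
    (noisy_lo, noisy_hi).
    """
    p = p or FilterParams()
    cycle = len(fg.flow_order)
    values = fg.flow_values
    usable = fg.usable_flows
    if usable % cycle:
        _log.warning("%s: %d usable flows is not a whole number of frames; final partial frame ignored",
                     fg.read_id, usable)
    cut: int | None = None
    trunc_reason = "none"
    for start in range(0, usable - cycle + 1, cycle):
        frame = values[start : start + cycle]
        if np.all(frame < p.low_signal):
            cut, trunc_reason = start, "no_signal_run"
            break
        if np.any(frame > p.large_flow):
            cut, trunc_reason = start, "large_flow"
            break
        if np.any((frame > p.noisy_lo) & (frame < p.noisy_hi)):
            cut, trunc_reason = start, "noisy_flow"
            break
    return _finalize(fg, cut, trunc_reason, p)


def flowwise_filter(
    fg: Flowgram,
    p: FilterParams | None = None,
    truncate: bool = True,
) -> tuple[FilterOutcome, Flowgram]:
    """Flow-by-flow flowgram filter.

    In truncate mode the flowgram is cut immediately before any flow
    that is (1) below ``low_signal`` with the following two flows also
    <= ``low_signal``, (2) above ``large_flow``, or (3) in
    [``noisy_lo``, ``noisy_hi``).  In no-truncate mode only the
    ``min_flows`` elimination applies and the flowgram passes through
    untouched.
    """
    p = p or FilterParams()
    if not truncate:
        remaining = fg.usable_flows
        if remaining < p.min_flows:
            out = FilterOutcome(fg.read_id, "eliminated", remaining, "too_few_flows")
            return out, fg
        return FilterOutcome(fg.read_id, "retained", remaining, "none"), fg
    values = fg.flow_values
    usable = fg.usable_flows
    n = len(values)
    cut: int | None = None
    trunc_reason = "none"
    for i in range(usable):
        v = values[i]
        if v < p.low_signal and i + 2 < n and values[i + 1] <= p.low_signal and values[i + 2] <= p.low_signal:
            cut, trunc_reason = i, "no_signal_run"
            break
        if v > p.large_flow:
            cut, trunc_reason = i, "large_flow"
            break
        if p.noisy_lo <= v < p.noisy_hi:
            cut, trunc_reason = i, "noisy_flow"
            break
    return _finalize(fg, cut, trunc_reason, p)


def quality_window_filter(
    sequence: str,
    qualities,
    window: int = 50,
    mean_q: float = 25.0,
    min_len: int = 150,
    max_len: int = 550,
    discard_truncated: bool = False,
) -> tuple[FilterOutcome, str]:
    """Sliding-window quality truncation with length bounds.

    The read is truncated at the start of the first window of
    ``window`` bases whose mean quality falls below ``mean_q``, then
    eliminated when its length is outside [``min_len``, ``max_len``].
    With ``discard_truncated`` any read that had a bad window is
    eliminated outright.  A window longer than the read disables the
    window test.
    """
    q = np.asarray(qualities, dtype=float)
    if len(q) != len(sequence):
        raise ValueError("qualities must have the same length as the sequence")
    read_id = ""
    cut: int | None = None
    if window <= len(q) and window > 0:
        means = np.convolve(q, np.ones(window), mode="valid") / window
        bad = np.nonzero(means < mean_q)[0]
        if len(bad):
            cut = int(bad[0])
    trunc_reason = "none"
    out_seq = sequence
    if cut is not None:
        out_seq = sequence[:cut]
        trunc_reason = "noisy_flow"  # quality analogue of the noisy criterion
        if discard_truncated:
            return FilterOutcome(read_id, "eliminated", len(out_seq), "noisy_flow", trunc_reason), out_seq
    if len(out_seq) < min_len:
        return FilterOutcome(read_id, "eliminated", len(out_seq), "too_few_flows", trunc_reason), out_seq
    if len(out_seq) > max_len:
        return FilterOutcome(read_id, "eliminated", len(out_seq), "too_many_flows", trunc_reason), out_seq
    return FilterOutcome(read_id, "retained", len(out_seq), trunc_reason, trunc_reason), out_seq


def attribution(out: FilterOutcome) -> str:
    """The criterion a filtering outcome is attributed to in reports:
    the truncation trigger when one fired, else the outcome's reason."""
    return out.trunc_reason if out.trunc_reason != "none" else out.reason


def filter_report(outcomes) -> pd.DataFrame:
    """Aggregate filtering outcomes into a per-criterion summary table.

    Rows: ``eliminated`` (reads thrown out, attributed to the criterion
    that triggered their truncation, or the length test when none did),
    ``truncated`` (retained reads that lost flows), ``retained_intact``.
    Columns: the criteria plus a ``total`` column.
    """
    criteria = [r for r in REASONS if r != "none"]
    rows = {
        status: dict.fromkeys(criteria + ["intact"], 0)
        for status in ("eliminated", "truncated", "retained_intact")
    }
    for out in outcomes:
        if out.status == "eliminated":
            rows["eliminated"][attribution(out)] += 1
        elif out.truncated:
            rows["truncated"][out.trunc_reason] += 1
        else:
            rows["retained_intact"]["intact"] += 1
    table = pd.DataFrame(rows).T
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table
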