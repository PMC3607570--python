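"""Interpret sequences from flowgrams.

Different 454 pipelines turned the same flow values into different
sequences because of two conventions that this module makes explicit:

* **Rounding** — a flow value contributes ``round(value)`` copies of its
  nucleotide.  Values whose two-decimal representation ends in ``.50``
  sit exactly on the rounding boundary: the instrument rounded these
  down a majority of the time (``half_down``), while several pipeline
  scripts rounded them up (``half_up``).  The two conventions differ
  only at those boundary flows.

* **N rule** — how runs of low-signal flows (< 0.50, i.e. no base
  callable) become ambiguous bases.  ``three_low`` emits one N per
  maximal run of at least three consecutive low flows (instrument
  style); ``four_low_framed`` emits an N only when a whole T-A-C-G
  frame is low; ``none`` emits nothing for low flows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from flowaudit.flowgram_io import Flowgram

_log = logging.getLogger(__name__)

#: signal below which a flow calls no base; shared with FilterParams.low_signal
LOW_SIGNAL = 0.50


@dataclass
class CalledRead:
    """A sequence interpreted from a flowgram.

    ``flow_of_base[i]`` is the 0-based flow index that produced base
    ``i``; an N maps to the first flow of its low-signal run.
    """

    read_id: str
    sequence: str
    flow_of_base: np.ndarray
    flowgram: Flowgram | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.flow_of_base = np.asarray(self.flow_of_base, dtype=int)
        if len(self.flow_of_base) != len(self.sequence):
            raise ValueError(
                f"{self.read_id}: flow_of_base length {len(self.flow_of_base)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if len(self.flow_of_base) > 1 and np.any(np.diff(self.flow_of_base) < 0):
            raise ValueError(f"{self.read_id}: flow_of_base must be non-decreasing")


def _incorporations(value: float, rounding: str) -> int:
    """Number of bases a flow value calls under the given half-rounding.

    The ``.50`` boundary is detected on the two-decimal text
    representation of the dialect, not on binary floating point.
    """
    cents = int(round(value * 100))
    if abs(value * 100 - cents) < 1e-6 and cents % 100 == 50:
        if rounding == "half_up":
            return cents // 100 + 1
        if rounding == "half_down":
            return cents // 100
        raise ValueError(f"unknown rounding {rounding!r}")
    if rounding not in ("half_up", "half_down"):
        raise ValueError(f"unknown rounding {rounding!r}")
    return int(math.floor(value + 0.5))


def call_bases(
    fg: Flowgram,
    rounding: str = "half_down",
    n_rule: str = "three_low",
    low_signal: float = LOW_SIGNAL,
) -> CalledRead:
    """Interpret a flowgram into a sequence.

    Only the first ``fg.usable_flows`` flows are interpreted.  Under
    ``three_low`` every maximal run of >= 3 consecutive flows all below
    ``low_signal`` yields a single N (regardless of run length — the
    true number of missing bases is unknowable); ``four_low_framed``
    requires the run to span a whole dispensation cycle (four flows,
    any phase), the stricter rule some preprocessors used.
    """
    if n_rule not in ("none", "three_low", "four_low_framed"):
        raise ValueError(f"unknown n_rule {n_rule!r}")
    cycle = len(fg.flow_order)
    values = fg.flow_values[: fg.usable_flows]
    min_run = 3 if n_rule == "three_low" else cycle
    bases: list[str] = []
    flow_of: list[int] = []
    i = 0
    n = len(values)
    # An N marks a base missed *between* incorporations: before the
    # first one, dark flows are normal (the first base may simply sit
    # later in the dispensation cycle); after the last one there is no
    # evidence any base follows.  So low runs only count strictly
    # inside the incorporating region.
    signal = np.nonzero(values >= low_signal)[0]
    last_signal = int(signal[-1]) if len(signal) else -1
    while i < n:
        v = values[i]
        if v < low_signal:
            run = 1
            while i + run < n and values[i + run] < low_signal:
                run += 1
            if n_rule != "none" and run >= min_run and bases and i < last_signal:
                if run >= 6:
                    # >= 6 dark flows span more than one full cycle; the
                    # single N stands in for an unknowable number of bases
                    _log.debug("%s: low run of %d flows at flow %d -> single N", fg.read_id, run, i)
                bases.append("N")
                flow_of.append(i)
            i += run
            continue
        count = _incorporations(float(v), rounding)
        nuc = fg.flow_nucleotide(i)
        bases.extend(nuc * count)
        flow_of.extend([i] * count)
        i += 1
    return CalledRead(
        read_id=fg.read_id,
        sequence="".join(bases),
        flow_of_base=np.asarray(flow_of, dtype=int),
        flowgram=fg,
    )


def flows_for_positions(read: CalledRead, positions) -> pd.DataFrame:
    """Flow evidence for base positions of a called read.

    For each 0-based sequence position, report the producing flow index
    (0-based), the dispensed nucleotide, the called base and the raw
    flow value — the evidence view used to judge whether a change made
    by a denoiser is supported by the flowgram.
    """
    if read.flowgram is None:
        raise ValueError(f"{read.read_id}: no flowgram attached")
    rows = []
    for pos in positions:
        if not 0 <= pos < len(read.sequence):
            raise IndexError(
                f"{read.read_id}: position {pos} out of range for length {len(read.sequence)}"
            )
        flow = int(read.flow_of_base[pos])
        rows.append(
            {
                "position": pos,
                "base": read.sequence[pos],
                "flow_index": flow,
                "flow_nucleotide": read.flowgram.flow_nucleotide(flow),
                "flow_value": float(read.flowgram.flow_values[flow]),
            }
        )
    return pd.DataFrame(rows, columns=["position", "base", "flow_index", "flow_nucleotide", "flow_value"])
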