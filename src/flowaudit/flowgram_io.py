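"""Text flowgram (sff.txt) parsing/writing and seeded flowgram simulation.

A *flowgram* is the ordered vector of light-signal intensities produced
by a 454 pyrosequencer, one value per nucleotide flow; the signal of a
flow is approximately the length of the homopolymer incorporated during
that flow.  The Titanium chemistry dispenses nucleotides in a repeating
T-A-C-G cycle, so four consecutive flows make up one *frame*.

The text dialect handled here is the one produced by the Roche ``sffinfo``
tool: a common header declaring the flow order, followed by one block per
read with ``Flowgram``, ``Flow Indexes``, ``Bases`` and clip fields.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

DEFAULT_FLOW_ORDER = "TACG"

_VALID_BASES = frozenset("ACGT")


class SffTextError(ValueError):
    """Raised when an sff.txt file cannot be parsed."""


@dataclass
class Flowgram:
    """One read's raw signal plus the instrument's interpretation of it.

    Parameters
    ----------
    read_id : str
        Record identifier.
    flow_values : numpy.ndarray
        Non-negative signal values, one per flow, in units of nominal
        incorporations (two decimals in the text dialect).
    flow_order : str
        The repeating dispensation cycle (default ``"TACG"``).
    called_bases : str or None
        The instrument's base call; absent for synthetic data that has
        not been base called.
    n_usable_flows : int or None
        Number of flows covered by the instrument's called read, derived
        from the last flow index referenced by the record's Flow Indexes
        line.  ``None`` means unknown, in which case :attr:`usable_flows`
        falls back to all flows.
    """

    read_id: str
    flow_values: np.ndarray
    flow_order: str = DEFAULT_FLOW_ORDER
    called_bases: str | None = None
    n_usable_flows: int | None = None

    def __post_init__(self) -> None:
        self.flow_values = np.asarray(self.flow_values, dtype=float)
        if self.flow_values.ndim != 1:
            raise ValueError(f"{self.read_id}: flow_values must be one-dimensional")
        if np.any(self.flow_values < 0):
            raise ValueError(f"{self.read_id}: flow values must be >= 0")
        if self.n_usable_flows is not None and self.n_usable_flows > len(self.flow_values):
            raise ValueError(
                f"{self.read_id}: n_usable_flows ({self.n_usable_flows}) exceeds "
                f"flow count ({len(self.flow_values)})"
            )

    @property
    def n_flows(self) -> int:
        return len(self.flow_values)

    @property
    def usable_flows(self) -> int:
        """Flows covered by the instrument call (fallback: all flows)."""
        return self.n_usable_flows if self.n_usable_flows is not None else self.n_flows

    def flow_nucleotide(self, index: int) -> str:
        """Nucleotide dispensed at 0-based flow ``index``."""
        return self.flow_order[index % len(self.flow_order)]

    def truncated(self, n_flows: int) -> "Flowgram":
        """A copy keeping only the first ``n_flows`` flows.

        The instrument base call is dropped because it no longer matches
        the signal; the sequence must be re-interpreted by a base caller.
        """
        n_flows = int(n_flows)
        if n_flows > self.n_flows:
            raise ValueError(f"{self.read_id}: cannot truncate {self.n_flows} flows to {n_flows}")
        return Flowgram(
            read_id=self.read_id,
            flow_values=self.flow_values[:n_flows].copy(),
            flow_order=self.flow_order,
            called_bases=None,
            n_usable_flows=min(self.usable_flows, n_flows),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Flowgram):
            return NotImplemented
        return (
            self.read_id == other.read_id
            and self.flow_order == other.flow_order
            and self.called_bases == other.called_bases
            and self.n_usable_flows == other.n_usable_flows
            and len(self.flow_values) == len(other.flow_values)
            and bool(np.all(self.flow_values == other.flow_values))
        )


@dataclass
class FlowgramSet:
    """An ordered collection of flowgrams sharing one flow order."""

    flow_order: str = DEFAULT_FLOW_ORDER
    flowgrams: list[Flowgram] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.flowgrams)

    def __iter__(self) -> Iterator[Flowgram]:
        return iter(self.flowgrams)

    def __getitem__(self, key: int) -> Flowgram:
        return self.flowgrams[key]

    def append(self, fg: Flowgram) -> None:
        if fg.flow_order != self.flow_order:
            raise ValueError(
                f"{fg.read_id}: flow order {fg.flow_order!r} differs from set's {self.flow_order!r}"
            )
        self.flowgrams.append(fg)

    def ids(self) -> list[str]:
        return [fg.read_id for fg in self.flowgrams]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FlowgramSet):
            return NotImplemented
        return self.flow_order == other.flow_order and self.flowgrams == other.flowgrams


# ---------------------------------------------------------------------------
# sff.txt parsing / writing
# ---------------------------------------------------------------------------

def parse_sff_text(path: str | Path | io.TextIOBase) -> FlowgramSet:
    """Parse an ``sffinfo``-style sff.txt file into a :class:`FlowgramSet`.

    The common header must declare ``Flow Chars`` (the full dispensation
    string); per-read blocks start with ``>read_id`` and carry
    ``Flowgram``, ``Flow Indexes`` and ``Bases`` lines.  Flow values are
    preserved at the printed two-decimal precision.  ``n_usable_flows``
    is the highest flow index referenced by the Flow Indexes line.

    Raises
    ------
    SffTextError
        On a malformed record (the error names the read and line) or a
        missing flow order declaration.
    """
    if isinstance(path, (str, Path)):
        with open(path) as handle:
            lines = handle.read().splitlines()
    else:
        lines = path.read().splitlines()

    flow_chars: str | None = None
    cycle: str | None = None
    records: list[Flowgram] = []

    i = 0
    n = len(lines)
    # Header: everything before the first '>'
    while i < n and not lines[i].startswith(">"):
        stripped = lines[i].strip()
        if stripped.startswith("Flow Chars:"):
            flow_chars = stripped.split(":", 1)[1].strip()
        i += 1

    if flow_chars is None:
        raise SffTextError("missing 'Flow Chars' declaration in common header")
    cycle = _repeating_cycle(flow_chars)

    while i < n:
        line = lines[i]
        if not line.startswith(">"):
            i += 1
            continue
        read_id = line[1:].split()[0]
        start_line = i + 1
        i += 1
        fields: dict[str, str] = {}
        while i < n and not lines[i].startswith(">"):
            stripped = lines[i].strip()
            if ":" in stripped:
                key, value = stripped.split(":", 1)
                fields[key.strip()] = value.strip()
            i += 1
        try:
            records.append(_record_from_fields(read_id, fields, cycle))
        except SffTextError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise SffTextError(f"malformed record {read_id!r} near line {start_line}: {exc}") from exc

    return FlowgramSet(flow_order=cycle, flowgrams=records)


def _repeating_cycle(flow_chars: str) -> str:
    """Shortest repeating unit of the full dispensation string."""
    for length in range(1, len(flow_chars) + 1):
        unit = flow_chars[:length]
        reps = math.ceil(len(flow_chars) / length)
        if (unit * reps)[: len(flow_chars)] == flow_chars:
            return unit
    return flow_chars


def _record_from_fields(read_id: str, fields: dict[str, str], cycle: str) -> Flowgram:
    if "Flowgram" not in fields:
        raise SffTextError(f"malformed record {read_id!r}: missing Flowgram line")
    try:
        values = np.array([float(tok) for tok in fields["Flowgram"].split()], dtype=float)
    except ValueError as exc:
        raise SffTextError(f"malformed record {read_id!r}: bad Flowgram value: {exc}") from exc

    n_usable: int | None = None
    if "Flow Indexes" in fields and fields["Flow Indexes"]:
        try:
            idx = [int(tok) for tok in fields["Flow Indexes"].split()]
        except ValueError as exc:
            raise SffTextError(f"malformed record {read_id!r}: bad Flow Indexes: {exc}") from exc
        if idx:
            n_usable = max(idx)  # indexes are 1-based in the dialect
            if n_usable > len(values):
                raise SffTextError(
                    f"malformed record {read_id!r}: flow index {n_usable} exceeds "
                    f"{len(values)} flows"
                )

    bases = fields.get("Bases") or None
    return Flowgram(
        read_id=read_id,
        flow_values=values,
        flow_order=cycle,
        called_bases=bases,
        n_usable_flows=n_usable,
    )


def write_sff_text(fset: FlowgramSet, path: str | Path | io.TextIOBase) -> None:
    """Write a :class:`FlowgramSet` in the sff.txt dialect.

    Output reparses to an equal set (round-trip); flow values are emitted
    with two decimals.
    """
    own = isinstance(path, (str, Path))
    handle = open(path, "w") if own else path
    try:
        max_flows = max((fg.n_flows for fg in fset), default=0)
        handle.write("Common Header:\n")
        handle.write(f"  # of Reads:    {len(fset)}\n")
        handle.write(f"  Flow Chars:    {_full_flow_chars(fset.flow_order, max_flows)}\n\n")
        for fg in fset:
            handle.write(f">{fg.read_id}\n")
            handle.write(f"  # of Flows:   {fg.n_flows}\n")
            handle.write("Flowgram:\t" + "\t".join(f"{v:.2f}" for v in fg.flow_values) + "\n")
            if fg.n_usable_flows is not None:
                handle.write(f"Flow Indexes:\t{fg.n_usable_flows}\n")
            if fg.called_bases is not None:
                handle.write(f"Bases:\t{fg.called_bases}\n")
            handle.write("\n")
    finally:
        if own:
            handle.close()


def _full_flow_chars(cycle: str, n_flows: int) -> str:
    if n_flows == 0:
        return cycle
    reps = math.ceil(n_flows / len(cycle))
    return (cycle * reps)[: max(n_flows, len(cycle))]


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Conditions for a synthetic flowgram cohort.

    The simulator emulates the error phenomena a flowgram filter must
    recognise: per-flow Gaussian signal noise, isolated "noisy" flows
    whose value falls in [0.50, 0.70), unrealistically large flows
    (> 6.49), and low-signal runs of three flows that force an ambiguous
    base call.  Injected phenomena are drawn per read as mutually
    exclusive events so that a truth table can attribute each read's
    filtering outcome to exactly one cause.

    Parameters
    ----------
    templates : sequence of str
        ACGT template sequences reads are drawn from.
    reads_per_template : int
        Reads simulated per template.
    noise_sd : float
        Standard deviation of the per-flow Gaussian signal noise
        (truncated at zero).  Default 0.05, small enough that noise
        alone never crosses a filter threshold.
    noisy_flow_rate : float
        Per-read probability of replacing one flow with a value drawn
        uniformly from [0.50, 0.70).
    large_flow_rate : float
        Per-read probability of replacing one flow with a value > 6.49.
    low_run_rate : float
        Per-read probability of zeroing a run of three consecutive
        flows, which forces an N call.
    seed : int
        Seed; identical config + seed gives bit-identical output.
    """

    templates: Sequence[str]
    reads_per_template: int = 10
    noise_sd: float = 0.05
    noisy_flow_rate: float = 0.0
    large_flow_rate: float = 0.0
    low_run_rate: float = 0.0
    seed: int = 0
    flow_order: str = DEFAULT_FLOW_ORDER

    def __post_init__(self) -> None:
        for name in ("noisy_flow_rate", "large_flow_rate", "low_run_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.noisy_flow_rate + self.large_flow_rate + self.low_run_rate > 1.0 + 1e-12:
            raise ValueError("injection rates must sum to at most 1 (events are exclusive)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.reads_per_template < 0:
            raise ValueError("reads_per_template must be >= 0")
        for t in self.templates:
            if not set(t) <= _VALID_BASES:
                bad = sorted(set(t) - _VALID_BASES)
                raise ValueError(f"template contains non-ACGT characters: {bad}")
        if not self.templates and self.reads_per_template > 0:
            raise ValueError("templates must be non-empty unless reads_per_template is 0")


def ideal_flowgram(sequence: str, flow_order: str = DEFAULT_FLOW_ORDER) -> np.ndarray:
    """Noise-free flow values for ``sequence``: each homopolymer's flow
    equals its length, all other flows are zero.  The result is padded
    with zero flows to a whole number of frames.
    """
    values: list[float] = []
    pos = 0
    n = len(sequence)
    cycle = len(flow_order)
    flow = 0
    while pos < n:
        nuc = flow_order[flow % cycle]
        if sequence[pos] == nuc:
            run = 1
            while pos + run < n and sequence[pos + run] == nuc:
                run += 1
            values.append(float(run))
            pos += run
        else:
            values.append(0.0)
        flow += 1
    while len(values) % cycle != 0:
        values.append(0.0)
    return np.asarray(values, dtype=float)


def simulate_flowgrams(
    cfg: SimulationConfig,
    keys: pd.DataFrame | None = None,
) -> tuple[FlowgramSet, pd.DataFrame]:
    """Simulate a flowgram cohort and its ground-truth table.

    If a key table is given (columns ``sample_id``, ``mid_tag``,
    ``primer_seq``; see :func:`flowaudit.demux.load_key_table`), each
    read's template is prefixed by the mid tag + primer of a key chosen
    round-robin, and the truth table records the assignment.

    Injected phenomena are placed downstream of the prefix flows so the
    sample identity and the filtering behaviour can be audited
    independently.  Flow positions in the truth table are 0-based.

    Returns
    -------
    (FlowgramSet, pandas.DataFrame)
        The truth table has one row per read: ``read_id``,
        ``template_id``, ``sample_id``, ``prefix``, ``event``
        (``none | noisy_flow | large_flow | low_run``), ``event_flows``
        (comma-joined 0-based flow positions, empty if none),
        ``n_usable_flows`` and ``sequence`` (prefix + template).
    """
    rng = np.random.default_rng(cfg.seed)
    fset = FlowgramSet(flow_order=cfg.flow_order)
    rows: list[dict] = []

    key_rows = None
    if keys is not None and len(keys):
        key_rows = keys.reset_index(drop=True)

    read_no = 0
    for t_idx, template in enumerate(cfg.templates):
        for _ in range(cfg.reads_per_template):
            read_id = f"SIM{read_no:06d}"
            sample_id = ""
            prefix = ""
            if key_rows is not None:
                krow = key_rows.iloc[read_no % len(key_rows)]
                sample_id = str(krow["sample_id"])
                prefix = str(krow["mid_tag"]) + str(krow["primer_seq"])
                if "M" in prefix:
                    # degenerate primer base: emit a concrete member so the
                    # flowgram is synthesisable; M = A or C
                    prefix = prefix.replace("M", "AC"[int(rng.integers(2))])
            seq = prefix + template
            values = ideal_flowgram(seq, cfg.flow_order)
            n_usable = _last_positive_flow(values) + 1
            prefix_flows = 0
            if prefix:
                prefix_flows = _last_positive_flow(ideal_flowgram(prefix, cfg.flow_order)) + 1

            if cfg.noise_sd > 0:
                values = np.maximum(values + rng.normal(0.0, cfg.noise_sd, size=len(values)), 0.0)

            event = "none"
            event_flows: list[int] = []
            lo = prefix_flows
            hi = n_usable
            u = rng.random()
            if hi - lo >= 4:  # room to inject without touching the prefix
                if u < cfg.noisy_flow_rate:
                    event = "noisy_flow"
                    pos = int(rng.integers(lo, hi))
                    values[pos] = rng.uniform(0.50, 0.70)
                    event_flows = [pos]
                elif u < cfg.noisy_flow_rate + cfg.large_flow_rate:
                    event = "large_flow"
                    pos = int(rng.integers(lo, hi))
                    values[pos] = rng.uniform(6.50, 9.99)
                    event_flows = [pos]
                elif u < cfg.noisy_flow_rate + cfg.large_flow_rate + cfg.low_run_rate:
                    event = "low_run"
                    pos = int(rng.integers(lo, hi - 2))
                    values[pos : pos + 3] = 0.0
                    event_flows = [pos, pos + 1, pos + 2]

            fg = Flowgram(
                read_id=read_id,
                flow_values=values,
                flow_order=cfg.flow_order,
                n_usable_flows=n_usable,
            )
            # Instrument-style call: half-down rounding, N on 3-flow low runs
            from flowaudit.base_caller import call_bases  # local import: avoid cycle

            fg.called_bases = call_bases(fg, rounding="half_down", n_rule="three_low").sequence
            fset.append(fg)
            rows.append(
                {
                    "read_id": read_id,
                    "template_id": f"T{t_idx}",
                    "sample_id": sample_id,
                    "prefix": prefix,
                    "event": event,
                    "event_flows": ",".join(str(p) for p in event_flows),
                    "n_usable_flows": n_usable,
                    "sequence": seq,
                }
            )
            read_no += 1

    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "template_id",
            "sample_id",
            "prefix",
            "event",
            "event_flows",
            "n_usable_flows",
            "sequence",
        ],
    )
    return fset, truth


def _last_positive_flow(values: np.ndarray) -> int:
    """0-based index of the last flow with signal >= 0.5 (i.e. calling a base)."""
    idx = np.nonzero(values >= 0.5)[0]
    return int(idx[-1]) if len(idx) else -1


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str).astype(
        {"n_usable_flows": int}
    )
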