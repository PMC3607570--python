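"""Multi-stage audit orchestration.

A *stage manifest* lists, in pipeline order, the reconstituted read
set (FASTA) at each stage of a denoising pipeline.  Running the audit
produces, for every consecutive stage pair and for (first, last), a
change table; an accordion report for every consecutive stage triple;
and per-stage length summaries — one reproducible report bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

_log = logging.getLogger(__name__)

from flowaudit.change_quant import (
    AlignParams,
    accordion_report,
    length_summary,
    positional_profile,
    quantify_set,
)


@dataclass
class StageManifest:
    """Ordered (label, fasta_path) stages; labels must be unique."""

    stages: list[tuple[str, Path]]

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.stages]
        if len(set(labels)) != len(labels):
            raise ValueError("stage labels must be unique")
        self.stages = [(label, Path(p)) for label, p in self.stages]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StageManifest":
        stages = []
        with open(path) as handle:
            for lineno, line in enumerate(handle, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}: line {lineno}: expected 'label<TAB>fasta'")
                stages.append((parts[0], Path(parts[1])))
        return cls(stages)


def run_audit(
    manifest: StageManifest,
    params: AlignParams | None = None,
    outdir: str | Path = "audit_out",
) -> dict[str, pd.DataFrame]:
    """Run the full audit over a stage manifest and write the bundle.

    Returns the report frames keyed by file stem; every frame is also
    written as TSV under ``outdir``.  Output is byte-identical across
    reruns with the same inputs and configuration.
    """
    params = params or AlignParams()
    for label, path in manifest.stages:
        if not path.exists():
            raise FileNotFoundError(f"stage {label!r}: missing file {path}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reports: dict[str, pd.DataFrame] = {}

    # provenance: every threshold in the header file
    config = pd.DataFrame(
        sorted(vars(params).items()), columns=["parameter", "value"]
    )
    reports["config"] = config

    labels = [label for label, _ in manifest.stages]
    paths = dict(manifest.stages)

    summary, hist = length_summary({label: paths[label] for label in labels})
    reports["lengths_summary"] = summary
    reports["lengths_histogram"] = hist

    pairs = list(zip(labels, labels[1:]))
    if len(labels) > 2:
        pairs.append((labels[0], labels[-1]))
    tables = {}
    for ref_label, q_label in pairs:
        table = quantify_set(paths[q_label], paths[ref_label], params, keep_alignments=True)
        tables[(ref_label, q_label)] = table
        stem = f"changes_{ref_label}_to_{q_label}"
        reports[stem] = table.to_frame()
        reports[stem + "_summary"] = table.summary()
        profile = positional_profile(table.records, iupac_tolerant=params.iupac_tolerant)
        reports[f"profile_{ref_label}_to_{q_label}"] = profile
        if table.eliminated:
            for read_id in table.eliminated:
                _log.info("stage=%s read_id=%s event=eliminated reason=absent_from_stage", q_label, read_id)
            reports[f"eliminated_{ref_label}_to_{q_label}"] = pd.DataFrame(
                {"read_id": table.eliminated}
            )
        flagged = [r.read_id for r in table.records if r.gap5]
        for read_id in flagged:
            _log.warning("stage=%s read_id=%s event=5prime_overhang reason=prefix_anomaly", q_label, read_id)

    for a, b, c in zip(labels, labels[1:], labels[2:]):
        try:
            reports[f"accordion_{a}_{b}_{c}"] = accordion_report(
                tables[(a, b)], tables[(b, c)], _net_table(tables, paths, a, c, params)
            )
        except ValueError:
            # read sets differ between steps (eliminations); skip the triple
            continue

    for stem, frame in reports.items():
        frame.to_csv(outdir / f"{stem}.tsv", sep="\t", index=False)
    return reports


def _net_table(tables, paths, first: str, last: str, params: AlignParams):
    if (first, last) in tables:
        return tables[(first, last)]
    return quantify_set(paths[last], paths[first], params)
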