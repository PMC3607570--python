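"""Shared fixtures: key tables, templates and simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from flowaudit.demux import SampleKey
from flowaudit.flowgram_io import SimulationConfig, simulate_flowgrams
from flowaudit.synthetic import random_sequence

PRIMERS = {
    "341F": "CCTACGGGAGGCAGCAG",
    "926R": "CCGTCAATTCMTTTGAGTTT",
    "968F": "AACGCGAAGAACCTTAC",
    "1401R": "CGGTGTGTACAAGGCCCGGGAACG",
}

MID_TAGS = [
    "ACGAGTGCGT",
    "ACGCTCGACA",
    "AGACGCACTC",
    "AGCACTGTAG",
]


@pytest.fixture(scope="session")
def sample_keys() -> list[SampleKey]:
    """Four samples x two primers = eight (sample, primer) bins."""
    keys = []
    for i, mid in enumerate(MID_TAGS):
        for primer_name in ("341F", "968F"):
            keys.append(
                SampleKey(
                    sample_id=f"S{i + 1}",
                    mid_tag=mid,
                    primer_name=primer_name,
                    primer_seq=PRIMERS[primer_name],
                )
            )
    return keys


@pytest.fixture(scope="session")
def key_frame(sample_keys) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": k.sample_id,
                "mid_tag": k.mid_tag,
                "primer_name": k.primer_name,
                "primer_seq": k.primer_seq,
            }
            for k in sample_keys
        ]
    )


@pytest.fixture(scope="session")
def templates() -> list[str]:
    """Synthetic amplicon templates, homopolymers capped at 4."""
    rng = np.random.default_rng(20130405)
    out = []
    while len(out) < 5:
        seq = random_sequence(rng, 420)
        if max(len(run) for run in _runs(seq)) <= 4:
            out.append(seq)
    return out


def _runs(seq: str) -> list[str]:
    runs = []
    current = seq[0]
    for c in seq[1:]:
        if c == current[-1]:
            current += c
        else:
            runs.append(current)
            current = c
    runs.append(current)
    return runs


@pytest.fixture(scope="session")
def clean_cohort(templates):
    """A 50-read noise-free cohort (no injections)."""
    cfg = SimulationConfig(templates=templates, reads_per_template=10, noise_sd=0.0, seed=7)
    return simulate_flowgrams(cfg)


@pytest.fixture(scope="session")
def injected_cohort(templates, key_frame):
    """A 200-read cohort with prefixes and injected filter triggers."""
    cfg = SimulationConfig(
        templates=templates,
        reads_per_template=40,
        noise_sd=0.05,
        noisy_flow_rate=0.15,
        large_flow_rate=0.10,
        low_run_rate=0.10,
        seed=11,
    )
    return simulate_flowgrams(cfg, key_frame)
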