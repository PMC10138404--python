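"""Shared fixtures: the synthetic study dataset is generated once per session."""

from __future__ import annotations

import pandas as pd
import pytest

from goosemethyl import annotation, dmr, synthetic

SEED = 1  # canonical demo seed used throughout the suite


@pytest.fixture(scope="session")
def dataset() -> synthetic.SyntheticDataset:
    """Default-scale synthetic study: 2 breeds x 3 stages x 3 replicates."""
    return synthetic.generate_dataset(seed=SEED)


@pytest.fixture(scope="session")
def gene_regions(dataset):
    return annotation.derive_all_gene_regions(
        dataset.genes, chrom_lengths=dataset.chrom_lengths
    )


@pytest.fixture(scope="session")
def e15_groups(dataset):
    """(STE, WZE) replicate call tables at the earliest stage."""
    return dataset.group_calls("STE", "E15"), dataset.group_calls("WZE", "E15")


@pytest.fixture(scope="session")
def e15_dmrs(e15_groups):
    calls_a, calls_b = e15_groups
    return dmr.call_dmrs(calls_a, calls_b)


@pytest.fixture(scope="session")
def null_config() -> synthetic.SimulationConfig:
    """Identical group surfaces: no DMRs, no breed/stage offsets."""
    return synthetic.SimulationConfig(
        n_dmrs=0,
        breed_offsets={"WZE": 0.0, "STE": 0.0},
        stage_offsets={
            "WZE": {"E15": 0.0, "E23": 0.0, "P1": 0.0},
            "STE": {"E15": 0.0, "E23": 0.0, "P1": 0.0},
        },
        promoter_levels={"WZE": 0.55, "STE": 0.55},
    )


@pytest.fixture(scope="session")
def null_dataset(null_config) -> synthetic.SyntheticDataset:
    return synthetic.generate_dataset(null_config, seed=3)


def overlap_count(truth: pd.DataFrame, detected: pd.DataFrame) -> int:
    """How many truth intervals are overlapped by >= 1 detected interval."""
    n = 0
    for r in truth.itertuples():
        hit = detected[
            (detected["chrom"] == r.chrom)
            & (detected["start"] < r.end)
            & (detected["end"] > r.start)
        ]
        n += int(len(hit) > 0)
    return n
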