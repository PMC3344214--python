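"""Shared fixtures: simulated datasets and pipeline runs reused across tests."""

from __future__ import annotations

import pytest

from msatphylo.pipeline import RunConfig, run_pipeline
from msatphylo.synthetic_data import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition simulated dataset (seed 42)."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def default_report(default_dataset):
    """Full pipeline run (no bootstrap) on the default dataset."""
    cfg = RunConfig(
        locus_configs=default_dataset.locus_configs,
        locus_order=[l.name for l in default_dataset.config.loci],
        records_by_locus=default_dataset.records,
        bootstrap_reps=0,
    )
    return run_pipeline(cfg)
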