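"""Shared fixtures: small synthetic datasets and the full-scale scenario runs."""

from __future__ import annotations

import pytest

from dupmine import generate_dataset, paper2021
from dupmine.epi import scenario_metrics


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale scenario (20k patients) for structural checks."""
    return paper2021(n_patients=20_000, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def midsize_dataset():
    """50k-patient dataset: enough candidate contacts for the kappa protocol."""
    return generate_dataset(paper2021(n_patients=50_000, seed=3))


N_SCENARIO_SEEDS = 20


@pytest.fixture(scope="session")
def scenario_runs():
    """Full-scale scenario recovery runs (200k patients, seeds 1..20).

    Returns a list of per-seed metric dicts from the end-to-end pipeline;
    datasets are discarded after each run to bound memory.
    """
    runs = []
    for seed in range(1, N_SCENARIO_SEEDS + 1):
        ds = generate_dataset(paper2021(n_patients=200_000, seed=seed))
        runs.append(scenario_metrics(ds))
        del ds
    return runs
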