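"""Shared fixtures: one default noisy simulation and one clean (noise-free,
error-free) simulation, each run through the full pipeline once per session."""

from __future__ import annotations

import warnings

import pytest

from condop.classify import TrainConfig
from condop.pipeline import analyze_condition
from condop.synthetic import SimConfig, simulate

SIM_SEED = 3

warnings.filterwarnings("ignore", message="The `probability` parameter was deprecated")


@pytest.fixture(scope="session")
def default_sim():
    """Default study conditions: Poisson noise, 10% annotation errors."""
    return simulate(SimConfig(seed=SIM_SEED))


@pytest.fixture(scope="session")
def default_result(default_sim):
    res = default_sim
    return analyze_condition(
        res.genome.genes,
        res.genome.cds,
        res.condition.track,
        res.genome.reference_operons,
        train_cfg=TrainConfig(seed=1),
    )


@pytest.fixture(scope="session")
def feature_table(default_result):
    return default_result.feature_table


@pytest.fixture(scope="session")
def clean_sim():
    """Ideal regime: noise off, perfect reference annotation."""
    return simulate(SimConfig(seed=SIM_SEED, noise="none", annotation_error_rate=0.0))


@pytest.fixture(scope="session")
def clean_result(clean_sim):
    res = clean_sim
    return analyze_condition(
        res.genome.genes,
        res.genome.cds,
        res.condition.track,
        res.genome.reference_operons,
        train_cfg=TrainConfig(seed=1),
    )
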