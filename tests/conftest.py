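"""Shared fixtures: small synthetic scenarios and reusable MCMC fits."""

from __future__ import annotations

import numpy as np
import pytest

import aphidpop as ap
from aphidpop.inference import MCMCConfig


@pytest.fixture(scope="session")
def truth() -> ap.CoefficientSet:
    return ap.default_truth()


@pytest.fixture(scope="session")
def small_experiment() -> ap.SyntheticDataset:
    """Two pure-clone treatments, two replicates: quick but non-trivial."""
    cfg = ap.ScenarioConfig(seed=5, replicates=2, treatments=("A", "B"))
    return ap.gen_experiment(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_experiment) -> ap.FieldDataset:
    return ap.dataset_from_synthetic(small_experiment)


@pytest.fixture(scope="session")
def small_fit(small_dataset) -> ap.PosteriorChains:
    """A short but converged fit of the small dataset, shared across tests."""
    cfg = MCMCConfig(chains=3, burnin=500, draws=1500, thin=1, seed=3)
    return ap.run_mcmc(small_dataset, cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
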