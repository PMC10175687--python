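"""Shared fixtures and independent numerical oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from teicopk import final_model, generate_dataset
from teicopk.population import PopulationModel


@pytest.fixture(scope="session")
def published_model() -> PopulationModel:
    return final_model()


@pytest.fixture(scope="session")
def small_cohort(published_model):
    """A 25-subject synthetic cohort shared by estimation tests."""
    rng = np.random.default_rng(20240)
    return generate_dataset(25, published_model, rng)
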