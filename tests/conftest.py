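"""Shared fixtures: published point estimates and small synthetic studies."""

import numpy as np
import pytest

from ecmopk.population import (
    FixedEffects,
    PopulationModel,
    RandomEffectsSpec,
    ResidualSpec,
)
from ecmopk.pk import PKParameters


@pytest.fixture(scope="session")
def table_params() -> PKParameters:
    """Published structural point estimates (RRT-branch clearance)."""
    return PKParameters(cl=5.1, vc=18.7, vp=13.2, q=21.0)


@pytest.fixture(scope="session")
def table_fixed() -> FixedEffects:
    return FixedEffects(5.1, 18.7, 13.2, 21.0, 1.89)


@pytest.fixture(scope="session")
def table_model(table_fixed) -> PopulationModel:
    return PopulationModel(
        fixed=table_fixed,
        random_effects=RandomEffectsSpec.from_cv_percent(51.6, 45.8, 28.7),
        residual=ResidualSpec(0.137, 2.3),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20140565)
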