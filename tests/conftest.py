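import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from microdiv.core import BirthDeathModel
from microdiv.mass_extinction import MassExtinctionModel, default_schedule
from microdiv.parameter_space import FeasibilityBounds, ParameterDomain


@pytest.fixture
def domain() -> ParameterDomain:
    return ParameterDomain()


@pytest.fixture
def bounds() -> FeasibilityBounds:
    return FeasibilityBounds()


@pytest.fixture
def bd_model() -> BirthDeathModel:
    return BirthDeathModel(t=4000.0)


@pytest.fixture
def me_model_full() -> MassExtinctionModel:
    """Mass-extinction model with intense events hitting every taxon."""
    return MassExtinctionModel(default_schedule(p=0.9, q=1.0))
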