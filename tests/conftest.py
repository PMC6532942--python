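import pytest

from remiflux import RegulationSet, ToySpec, build_remi_problem, toy_model


@pytest.fixture
def chain3():
    """Linear pathway: EX_in -> R1 -> R2 -> R3 -> {EX_out, BIOMASS}, uptake <= 10."""
    return toy_model(ToySpec(topology="chain", length=3))


@pytest.fixture
def diamond():
    return toy_model(ToySpec(topology="diamond"))


@pytest.fixture
def hub():
    """One metabolite M with producers v1, v2 and consumers v3, v4."""
    return toy_model(ToySpec(topology="hub"))


@pytest.fixture
def chain3_problem(chain3):
    return build_remi_problem(chain3, RegulationSet())
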