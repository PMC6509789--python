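import pytest

from paretoflux import FluxObjective, make_toy


@pytest.fixture
def toy():
    """Toy phototroph, photon cap 50, acetate cap 10 (the study defaults)."""
    return make_toy(P=50.0, A=10.0)


@pytest.fixture
def growth_objective():
    return FluxObjective.for_reaction("EX_biomass", label="growth")


@pytest.fixture
def h2_objective():
    return FluxObjective.for_reaction("EX_h2", label="h2")
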