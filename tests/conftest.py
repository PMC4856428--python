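import pytest

from ctxrecon.classify import classify_reactions
from ctxrecon.fixtures import (
    FIG1_MEDIUM,
    FixtureSpec,
    make_fig1_analogue,
    make_random_fixture,
)
from ctxrecon.gpr import parse_gpr
from ctxrecon.model import MetabolicModel, Reaction, apply_medium, split_reversible


@pytest.fixture(scope="session")
def fig1():
    """The spurious-cycle showcase model with its H/M/L classification."""
    model, classification = make_fig1_analogue()
    return model, classification


@pytest.fixture(scope="session")
def fig1_split(fig1):
    model, _ = fig1
    return apply_medium(split_reversible(model), FIG1_MEDIUM)


@pytest.fixture
def chain_model():
    """Linear chain: uptake(<=10) -> conversion -> biomass; optimum 10."""
    return MetabolicModel(
        compounds=["A", "B"],
        reactions=[
            Reaction("EX_A", {"A": -1}, -10, 1000, is_exchange=True),
            Reaction("conv", {"A": -1, "B": 1}, 0, 1000, gpr=parse_gpr("gc")),
            Reaction("biomass", {"B": -1}, 0, 1000),
        ],
        biomass_id="biomass",
    )


@pytest.fixture
def random_fixture_factory():
    def build(seed, **kwargs):
        model, profile, meta = make_random_fixture(FixtureSpec(seed=seed, **kwargs))
        classification = classify_reactions(model, profile)
        return model, profile, classification, meta

    return build
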